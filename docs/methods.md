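# Methods

This note documents the models implemented in `smtirf`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Dwell-time analysis

### Recording convention

A membrane-binding event observed in *n* consecutive frames at frame
interval Δt (default 0.052 s) is assigned the recorded dwell
(*n* − 1)·Δt. Tracks seen in a single frame carry no dwell information
under this convention and are removed by the standard track filters
(minimum two frames), so the shortest recordable dwell is one frame
interval. Tracks already present in the first movie frame or still
present in the last are removed as censored; no further
survival-analysis censoring correction is applied, which is adequate
when movies are long relative to the dwell constants (the regime the
filters are designed for).

### Survival curve and fit space

The empirical survival function S(t) = #(dwells ≥ t)/n is evaluated on
the Δt grid from the minimum recorded dwell to one bin past the
maximum. Fits minimize the unweighted sum of squared residuals of
log₁₀ S against the log₁₀ of

- one component: f(x) = e^(−x/τ), or
- two components: f(x) = α·e^(−x/τ₁) + (1 − α)·e^(−x/τ₂), τ₁ ≤ τ₂,

with x measured **from the minimum recorded dwell**. This re-zeroing is
deliberate: for frame-discretized data, P(recorded ≥ kΔt) equals the
raw mixture survival at kΔt, and conditioning on surviving the first
frame then re-zeroing yields *exactly* a two-exponential mixture with
the same τ₁, τ₂ and weight α′ = α·e^(−Δt/τ₁)/(α·e^(−Δt/τ₁) +
(1−α)·e^(−Δt/τ₂)). Recovered time constants are therefore unbiased by
discretization; the recovered weight differs from the generating α by
the one-frame conditioning shift (≈1–2% when τ ≫ Δt).

### Tail handling

Two classes of grid points are excluded from the log-space fit:

- zero-survival points (log undefined), and
- points supported by fewer than 10 surviving events (configurable via
  `min_survivors`).

The second exclusion matters. Between rare tail order statistics the
empirical survival is constant across long grid runs — a single
longest-lived particle can contribute hundreds of nearly identical,
nearly information-free points. In an unweighted fit those points
dominate the SSR: on simulated well-separated mixtures the full-grid
fit preferred a grossly wrong optimum (α ≈ 0.996, τ₁ ≈ the overall
decay) whose SSR was 20× smaller than at the generating parameters.
Requiring ≥ 10 survivors (log₁₀ S sampling SD ≲ 0.15) restores median
parameter-recovery bias to a few percent at n ≈ 3000–5000 without
introducing any weighting.

### Initialization and model selection

Multistart least squares (`scipy.optimize.least_squares`, TRF, bounds
α ∈ [0,1], τ > 0): τ₁ starts at {0.25, 0.5, 1}× the first grid time
where survival drops below 1/e, τ₂ at {2, 5, 10}×τ₁, α ∈ {0.3, 0.7};
the converged start with the lowest SSR wins, ties broken by start
order. The wide τ grid is required for mixtures separated by factors
of ~10, which a narrower grid misses.

`select_dwell_model` keeps the two-component fit only when the
extra-sum-of-squares F-test (2 extra parameters) gives p < 0.01 **and**
α ∈ [0.01, 0.99] **and** τ₂/τ₁ ≥ 2. The separation guard is set at 2
rather than a smaller value because the log-space residuals are
heteroskedastic, which makes the F statistic anti-conservative: pure
single-exponential data occasionally produce a nominally very
significant second component with τ₂/τ₁ ≈ 1.7, while genuinely
resolvable mixtures sit well above 2. With these guards, simulated
single-exponential and well-separated-mixture data are each classified
correctly in ≥ 95% of seeds (verified in the test suite).

### Uncertainties and fold changes

Optional case-resampling bootstrap (seeded, resampling dwell events)
supplies parameter SDs. These quantify sampling error within one data
set, which is a different quantity from spread across technical
replicates. Fold changes between conditions are ratios of mean dwell
times — the sample mean, or the model mean α·τ₁ + (1−α)·τ₂ — not
ratios of τ₁; both means are reported because real pipelines disagree
on which to print.

## Step-size diffusion analysis

Frame-to-frame displacements (gap-spanning pairs excluded, so every
step shares one lag) are binned from zero at 0.01 µm and converted to
probability density (fraction/bin width). The one- and two-species
Rayleigh models are fit by unweighted least squares on bin centers,
with multistart D ∈ {0.1, 0.5, 1.5}×(mean r²/4τ) and α ∈ {0.3, 0.7}
(for two species, only ordered start pairs are used), canonical
ordering D₁ ≤ D₂. The fits are cross-checked in the test suite against
an independent EM maximum-likelihood estimator on the unbinned steps.

Localization error is **not** part of the model (it adds ~σ_loc²/τ to
apparent D); the simulator renders movies with configurable photon
budgets precisely so this bias can be measured end to end. Bin counts
are not used as weights; with ≥ 10,000 steps the unweighted fit and
the EM oracle agree within a few percent.

## Spot detection, linking, filtering

Detection computes the scale-normalized Laplacian-of-Gaussian response
−σ²·LoG per frame, takes local maxima above a quality threshold, and
refines each to sub-pixel precision by quadratic interpolation of the
response peak along each axis (adequate for the downstream statistics;
Gaussian MLE localization is deliberately out of scope). Linking is
gated minimum-total-squared-displacement bipartite assignment per
consecutive frame pair (Hungarian algorithm), with optional gap closing
up to a configurable number of missed frames (gate variance scaled by
the gap length). In the sparse single-molecule regime this reproduces
what a full linear-assignment-problem tracker does, since merges and
splits are negligible; deterministic (frame, spot) ordering breaks
cost ties. Track filters: drop tracks alive at movie start or end,
shorter than 2 observed frames, exceeding an optional total
displacement cap, or entering an optional field-edge margin (default
suggestion 3σ of the PSF, as edge-clipped PSFs localize poorly).

On simulated movies at SNR ≈ 5 and sparse density the full
simulate → render → detect → link → filter chain recovers ≥ 95% of
ground-truth tracks and the generating dwell and diffusion constants
within 25% (test suite).

## Surface densities

`density_from_particle_counts` divides the per-area count of a dilute
labeled subpopulation by the labeled fraction; per-frame counts are
averaged first and a Poisson standard error on the mean is attached.
Incomplete dye labeling is treated as part of the labeled fraction.
`lipid_surface_density` converts a bilayer mole fraction with a
per-lipid footprint (0.72 nm², phosphatidylcholine) counting only the
solution-facing leaflet — the accessible substrate pool for a
membrane-bound enzyme; 2 mol% gives 2.8 × 10⁴ lipids/µm². Dye
photophysics (blinking, dark fractions) is not corrected for.

## Kinetics

Sensor intensity is assumed proportional to product density (sensor
occupancy ≪ 1% of product lipids, so no binding-isotherm correction).
Normalization maps a baseline window to 0 and a plateau window to 1,
clipping to [0, 1.05] with a flag; the reaction must reach its plateau
within the trace for the normalization to be meaningful. The initial
rate is the OLS slope over the maximal prefix with product ≤ 10% of
substrate (configurable `depletion_cap`). Under the first-order
depletion law P(t) = S₀(1 − e^(−kcat·E·t/S₀)) this secant
underestimates the true tangent kcat·E by ≈ cap/2 (~5% at the default
cap) — a known, documented bias chosen as the tradeoff against noise
amplification in shorter windows; recovered kcat values inherit it.
kcat is the initial rate divided by the enzyme surface density
(measured by single-molecule counting or user-supplied) and is
invariant to the sensor's arbitrary intensity scale.

Two-phase (ATP-spike) comparisons measure enzyme density in the
pre-ATP window and rates in the post-ATP window; the
density-normalized activation fold (rate_test/rate_ref)/(E_test/E_ref)
cancels the secant bias between conditions because both windows span
the same depletion fraction.

Adsorption/equilibration traces are fit to I(t) = plateau·(1 −
e^(−k_obs·t)) by bounded least squares with data-driven starting
values; traces shorter than ~3/k_obs are accepted but poorly
constrain the plateau.

## Synthetic-data generators

The simulators emulate: Poisson arrivals uniform over the field,
two-population exponential dwells discretized at the frame interval,
two-species Brownian steps (dwell and diffusion components drawn
independently by default, with optional coupling), optional
photobleaching (exponential hazard truncating observation) and a
minimal membrane-hopping model (on unbinding, rebind within a radius
with fixed probability, continuing the track), pixel-integrated
Gaussian PSF rendering with Poisson amplitude and background plus
Gaussian read noise, first-order substrate-depleting catalysis traces
with multiplicative sensor noise, and pseudo-first-order adsorption
traces. Defaults reflect the experimental regime the analyses target:
52 ms frames, 0.16 µm pixels, ~0.2 enzymes/µm², 2.8 × 10⁴ substrate
lipids/µm², 2% sensor noise.

Not emulated: EMCCD gain-register (excess) noise, astigmatic/3-D PSFs,
stage drift, dye blinking/photophysics, state switching within a
track, and localization error injected into track tables (it arises
only via the render→detect path). Passing recovery tests therefore
demonstrates estimator correctness under the stated generative model,
not robustness to every artifact of real microscope data.

All simulators take one explicit integer seed and are bit-reproducible;
pipelines derive per-stage seeds as crc32(global_seed, stage_name), so
adding a stage never shifts another stage's draws.

## Problem sizes

Recovery checks use the sample sizes the analyses are designed for:
4698 and 3421 dwell events, 20,000 displacement steps, 1500-point
catalysis traces spanning five depletion time constants, with medians
over 20 seeded replicates for stochastic quantities. These sizes give
sampling error comfortably inside the tolerances asserted in the test
suite while keeping a full run to seconds.

## Known limitations

- Dwell fitting assumes at most two exponential components and no
  within-track state changes.
- The rebinding model is a minimal formalization (fixed probability,
  uniform disk); real membrane hopping is diffusion-limited.
- No photobleaching correction of dwell times: with bleaching on,
  recorded dwells reflect min(unbinding, bleaching).
- The diffusion fit ignores localization error and motion blur.
- Kinetics assumes a single substrate density per experiment; no
  Michaelis–Menten K_M estimation, no sensor photobleaching
  correction.
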