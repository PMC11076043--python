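# smtirf

Single-molecule TIRF analysis for supported-lipid-bilayer experiments:
dwell-time survival analysis, step-size diffusion mixtures, spot
detection and trajectory linking, absolute surface-density calibration,
and biosensor-based lipid-kinase kinetics — plus seeded simulators for
every input, so each analysis stage can be validated by parameter
recovery against known ground truth.

## Who this is for

Labs that watch individual fluorescently labeled proteins bind, diffuse
on, and catalyze reactions at supported lipid bilayers (SLBs) by total
internal reflection fluorescence (TIRF) microscopy. The canonical
experiment: a lipid kinase such as PI3Kβ is recruited to a bilayer by
membrane-tethered activators (phosphotyrosine peptides, GTPases, GβGγ),
single molecules are tracked frame by frame, and bulk biosensor
fluorescence reports product-lipid formation. The package turns
TrackMate-style track tables (or raw TIFF movies) and two-column sensor
traces into membrane residence times, diffusion coefficients, absolute
densities, and per-enzyme catalytic rates.

## The models

**Dwell times.** A particle tracked in *n* frames at frame interval Δt
has recorded dwell (*n* − 1)·Δt (two-frame minimum). The empirical
survival function 1 − CDF, binned at Δt, is fit in log₁₀ space to

    f(x) = α·e^(−x/τ₁) + (1 − α)·e^(−x/τ₂)

(or a single exponential e^(−x/τ)), where α is the fraction of
fast-dissociating molecules with time constant τ₁ ≤ τ₂. An
extra-sum-of-squares F-test with degeneracy guards chooses between the
one- and two-component forms. Condition-to-condition fold changes use
the mean dwell (α·τ₁ + (1 − α)·τ₂ for the model), not τ₁ alone.

**Diffusion.** Frame-to-frame displacements r of a 2-D Brownian species
with coefficient D at lag τ follow the Rayleigh density
f(r) = r/(2Dτ)·exp(−r²/4Dτ); a two-species membrane population gives

    f(r) = α·r/(2D₁τ)·e^(−r²/4D₁τ) + (1−α)·r/(2D₂τ)·e^(−r²/4D₂τ)

fit to the binned step-size density (0.01 µm bins), with α the weight
of the slow species D₁.

**Surface densities.** Counting a dilute labeled fraction φ of a
membrane species gives total density (counts/area)/φ. Lipid densities
come from the bilayer mole fraction and a 0.72 nm² per-lipid footprint,
counting the solution-facing leaflet: 2 mol% → 2.8 × 10⁴ lipids/µm².

**Kinetics.** A lipid-sensor trace is normalized from baseline (0) to
plateau (1), scaled by the total product density the plateau
represents, and the initial rate is the least-squares slope over the
early window (product ≤ 10% of substrate). The per-enzyme rate is

    kcat = initial rate / enzyme surface density    [lipids/s·enzyme]

and the density-normalized activation fold between two conditions is
(rate_test/rate_ref)/(density_test/density_ref) — the ratio of
per-enzyme rates, which separates allosteric activation from mere
enhanced membrane recruitment.

## Worked example

Simulate a dwell-time experiment from known mixture constants
(α = 0.54, τ₁ = 0.55 s, τ₂ = 1.44 s, n = 4698 events at 52 ms frames),
then recover them; likewise for diffusion and kinetics:

```python
import numpy as np
import smtirf as sm

sample = sm.simulate_dwell_sample(
    n=4698, alpha=0.54, tau1_s=0.55, tau2_s=1.44,
    frame_interval_s=0.052, min_frames=2, seed=0,
)
fit = sm.fit_survival(sample, n_components=2)
print(f"alpha = {fit.alpha:.3f}")
print(f"tau1  = {fit.tau1_s:.3f} s")
print(f"tau2  = {fit.tau2_s:.3f} s")

steps = sm.simulate_step_sample(
    20_000, alpha=0.6, D1_um2_s=0.23, D2_um2_s=0.88, lag_s=0.052, seed=0)
dfit = sm.fit_step_distribution(steps, n_species=2)
print(f"D1 = {dfit.D1_um2_s:.3f} um2/s, D2 = {dfit.D2_um2_s:.3f} um2/s, "
      f"alpha = {dfit.alpha:.3f}")

S0, E, kcat = 2.8e4, 0.2, 57.0          # substrate/µm², enzymes/µm², truth
tc = S0 / (kcat * E)
cfg = sm.CatalysisSimConfig(
    kcat_per_enzyme=kcat, enzyme_density=E, substrate_density0=S0,
    t_grid_s=tuple(np.linspace(0, 5 * tc, 1500)), noise_sd_frac=0.02, seed=0)
res = sm.kcat_from_trace(
    sm.simulate_catalysis_trace(cfg),
    baseline_window=(0, 0.01 * tc), plateau_window=(4.5 * tc, 5 * tc),
    total_density=S0, enzyme_density=E)
print(f"initial rate = {res.initial_rate_per_um2_s:.2f} lipids/um2/s")
print(f"kcat = {res.kcat_per_s:.1f} lipids/s per enzyme")
```

Output:

```
alpha = 0.460
tau1  = 0.451 s
tau2  = 1.353 s
D1 = 0.223 um2/s, D2 = 0.876 um2/s, alpha = 0.581
initial rate = 10.82 lipids/um2/s
kcat = 54.1 lipids/s per enzyme
```

A single realization of 4698 dwell events carries real sampling error —
here τ₂ comes back 1.35 s against a generating 1.44 s; the median over
20 seeds lands within a few percent (see below). The recovered kcat of
54.1 sits ~5% below truth because the 10%-depletion secant slope
slightly underestimates the true initial tangent (see
`docs/methods.md`). The same analyses are scriptable from the shell
via the `smtirf` CLI (`smtirf simulate`, `smtirf track`, `smtirf dwell
fit`, `smtirf diffusion fit`, `smtirf kinetics kcat`, `smtirf run
config.yaml`).

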