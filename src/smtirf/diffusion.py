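"""Step-size diffusion analysis: Rayleigh one/two-species mixture fits.

For 2-D Brownian motion with diffusion coefficient D observed at lag τ,
the frame-to-frame displacement r follows a Rayleigh density

    f(r) = r/(2Dτ) · exp(−r²/(4Dτ)),

and a membrane population with two diffusive species gives the mixture

    f(r) = α·r/(2D₁τ)·exp(−r²/(4D₁τ)) + (1−α)·r/(2D₂τ)·exp(−r²/(4D₂τ)),

with α the weight of the slow species D₁ (canonical ordering D₁ ≤ D₂).
Fits are unweighted least squares of the binned probability density
(bin width 0.01 µm from zero, frequency divided by bin width) against
the model evaluated at bin centers.  Localization error is not part of
the model; the simulators can inject it so its bias is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .errors import FitError, InputError, ParameterError
from .tracks import TrackSet


@dataclass
class StepSample:
    """Frame-to-frame displacements (µm) at a single lag."""

    displacements_um: np.ndarray
    lag_s: float

    def __post_init__(self):
        self.displacements_um = np.asarray(self.displacements_um, dtype=float)
        if self.lag_s <= 0:
            raise ParameterError("lag_s must be > 0")
        if self.displacements_um.size == 0:
            raise InputError("empty step sample")
        if np.any(self.displacements_um < 0):
            raise InputError("displacements must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(self.displacements_um.size)


@dataclass
class StepHistogram:
    """Binned step-size probability density (fraction per µm)."""

    bin_centers_um: np.ndarray
    density: np.ndarray
    bin_width_um: float
    n_steps: int


@dataclass
class DiffMixtureFit:
    """Fitted step-size model; alpha weights the slow species D1."""

    n_species: int
    alpha: float
    D1_um2_s: float
    D2_um2_s: Optional[float]
    lag_s: float
    ssr: float
    n_steps: int

    def model_density(self, r):
        r = np.asarray(r, dtype=float)
        return _mixture_density(
            r, self.alpha, self.D1_um2_s, self.D2_um2_s, self.lag_s, self.n_species
        )

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "alpha": self.alpha,
            "D1_um2_s": self.D1_um2_s,
            "D2_um2_s": self.D2_um2_s,
            "lag_s": self.lag_s,
            "ssr": self.ssr,
            "n_steps": self.n_steps,
        }


def _rayleigh_density(r, D, lag):
    s2 = 2.0 * D * lag  # per-axis variance
    return r / s2 * np.exp(-(r**2) / (2.0 * s2))


def _mixture_density(r, alpha, D1, D2, lag, n_species):
    if n_species == 1:
        return _rayleigh_density(r, D1, lag)
    return alpha * _rayleigh_density(r, D1, lag) + (1.0 - alpha) * _rayleigh_density(
        r, D2, lag
    )


# ---------------------------------------------------------------------------
# operations


def compute_steps(tracks: TrackSet) -> StepSample:
    """Euclidean displacements between consecutive observed frames.

    Pairs spanning a linking gap (frame difference > 1) are excluded so
    every displacement shares the single-frame lag the mixture model
    assumes.
    """
    if len(tracks) == 0:
        raise InputError("empty track set")
    steps = []
    for t in tracks:
        if len(t) < 2:
            continue
        df = np.diff(t.frames)
        dx = np.diff(t.x)
        dy = np.diff(t.y)
        keep = df == 1
        if np.any(keep):
            steps.append(np.hypot(dx[keep], dy[keep]))
    if not steps:
        raise InputError("no single-frame steps in track set")
    return StepSample(
        displacements_um=np.concatenate(steps),
        lag_s=tracks.acquisition.frame_interval_s,
    )


def step_density(sample: StepSample, bin_width_um: float = 0.01) -> StepHistogram:
    """Histogram of step sizes as probability density.

    Bins start at 0 with fixed width (default 0.01 µm); density is
    (count/n)/bin_width, so it integrates to 1.  The final partial bin
    is retained.
    """
    if bin_width_um <= 0:
        raise ParameterError("bin_width_um must be > 0")
    r = sample.displacements_um
    n_bins = int(np.floor(r.max() / bin_width_um)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um
    counts, _ = np.histogram(r, bins=edges)
    density = counts / sample.n_steps / bin_width_um
    centers = 0.5 * (edges[:-1] + edges[1:])
    return StepHistogram(
        bin_centers_um=centers,
        density=density,
        bin_width_um=bin_width_um,
        n_steps=sample.n_steps,
    )


def fit_step_distribution(
    sample: StepSample, n_species: int, bin_width_um: float = 0.01
) -> DiffMixtureFit:
    """Fit the binned step-size density to the one- or two-species model.

    Multistart least squares over D ∈ {0.1, 0.5, 1.5}·D̂ with
    D̂ = mean(r²)/(4τ) (the method-of-moments single-species estimate)
    and α ∈ {0.3, 0.7}; canonical ordering D₁ ≤ D₂ with α the slow-species
    weight.
    """
    if n_species == 2 and sample.n_steps < 500:
        raise InputError("need >= 500 steps for a 2-species fit")
    r = sample.displacements_um
    if np.allclose(r, 0.0):
        raise FitError("degenerate step sample (all steps zero)")
    hist = step_density(sample, bin_width_um)
    return fit_step_histogram(hist, sample.lag_s, n_species)


def fit_step_histogram(
    hist: StepHistogram, lag_s: float, n_species: int
) -> DiffMixtureFit:
    """Fit a binned density (empirical or analytic) to the Rayleigh mixture."""
    if n_species not in (1, 2):
        raise ParameterError("n_species must be 1 or 2")
    rc, dens = hist.bin_centers_um, hist.density
    lag = lag_s
    # method-of-moments D̂ from the histogram itself
    d_hat = float(
        np.sum(rc**2 * dens) * hist.bin_width_um / (4.0 * lag)
    )
    if d_hat <= 0:
        raise FitError("degenerate step histogram")

    if n_species == 1:

        def resid(p):
            return _rayleigh_density(rc, p[0], lag) - dens

        best = None
        for scale in (0.1, 0.5, 1.5):
            res = optimize.least_squares(
                resid, [scale * d_hat], bounds=([1e-9], [np.inf]), method="trf"
            )
            ssr = float(np.sum(res.fun**2))
            if res.success and (best is None or ssr < best[1] - 1e-16):
                best = (res.x, ssr)
        if best is None:
            raise FitError("one-species step fit failed to converge")
        return DiffMixtureFit(
            n_species=1,
            alpha=1.0,
            D1_um2_s=float(best[0][0]),
            D2_um2_s=None,
            lag_s=lag,
            ssr=best[1],
            n_steps=hist.n_steps,
        )

    def resid2(p):
        a, d1, d2 = p
        return _mixture_density(rc, a, d1, d2, lag, 2) - dens

    best = None
    for s1 in (0.1, 0.5, 1.5):
        for s2 in (0.1, 0.5, 1.5):
            if s2 <= s1:
                continue
            for a in (0.3, 0.7):
                res = optimize.least_squares(
                    resid2,
                    [a, s1 * d_hat, s2 * d_hat],
                    bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]),
                    method="trf",
                )
                ssr = float(np.sum(res.fun**2))
                if res.success and (best is None or ssr < best[1] - 1e-16):
                    best = (res.x, ssr)
    if best is None:
        raise FitError("two-species step fit failed to converge")
    a, d1, d2 = best[0]
    if d1 > d2:  # canonical ordering: D1 <= D2, alpha weights D1
        d1, d2, a = d2, d1, 1.0 - a
    return DiffMixtureFit(
        n_species=2,
        alpha=float(a),
        D1_um2_s=float(d1),
        D2_um2_s=float(d2),
        lag_s=lag,
        ssr=best[1],
        n_steps=hist.n_steps,
    )


def summarize_mobility(sample: StepSample) -> dict:
    """Order statistics and moments of the step sizes.

    Condition-to-condition mobility reductions are ratios of mean steps.
    For a single Rayleigh species the median is sqrt(4Dτ·ln 2).
    """
    r = sample.displacements_um
    return {
        "median_step_um": float(np.median(r)),
        "mean_step_um": float(np.mean(r)),
        "mean_r2_um2": float(np.mean(r**2)),
        "n_steps": sample.n_steps,
        "lag_s": sample.lag_s,
    }
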