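"""Dwell-time survival analysis with exponential-mixture fits.

Single-molecule membrane residence times are measured as the number of
frames a particle is tracked.  The convention used throughout the
package is

    recorded dwell = (observed frames − 1) · Δt,

with a two-frame minimum, so the shortest observable dwell equals one
frame interval.  The empirical survival function (1 − CDF) is evaluated
on the Δt grid, and its log₁₀ is fit by unweighted nonlinear least
squares to

    f(x) = α·exp(−x/τ₁) + (1 − α)·exp(−x/τ₂)         (two components)
    f(x) = exp(−x/τ)                                  (one component)

where x is time since the minimum recorded dwell.  Measuring x from the
minimum dwell makes the model exact for frame-discretized exponential
mixtures: conditioning an exponential mixture on surviving the first
frame and re-zeroing returns a mixture with the *same* time constants
and a weight shifted to α·e^(−Δt/τ₁)/f(Δt).  Recovered τ's are
therefore unbiased by discretization; α inherits a ≲2% one-frame shift
for time constants much longer than Δt.

Zero-survival tail points are excluded from the fit (their log is
undefined).  Fits use multistart initialization with a deterministic
start order; the returned components are canonically ordered τ₁ ≤ τ₂
with α the weight of the fast (τ₁) component.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .errors import FitError, InputError, ParameterError
from .tracks import TrackSet


# ---------------------------------------------------------------------------
# containers


@dataclass
class DwellSample:
    """Recorded dwell durations (multiples of the frame interval)."""

    durations_s: np.ndarray
    frame_interval_s: float

    def __post_init__(self):
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be > 0")
        if self.durations_s.size == 0:
            raise InputError("empty dwell sample")
        # durations are >= one frame interval under the 2-frame minimum,
        # but sub-minimum samples (min_frames=0 simulations) are legal
        if np.any(self.durations_s < 0):
            raise InputError("durations must be >= 0")

    @property
    def n(self) -> int:
        return int(self.durations_s.size)

    def checksum(self) -> str:
        return hashlib.sha1(np.sort(self.durations_s).tobytes()).hexdigest()


@dataclass
class SurvivalCurve:
    """Empirical 1−CDF on the Δt grid.

    ``survival[0]`` is 1 at the minimum recorded dwell; values are
    non-increasing and reach 0 one bin beyond the longest dwell.
    """

    times_s: np.ndarray
    survival: np.ndarray
    n: int

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)

    def nonzero(self, min_survival: float = 0.0):
        """(times, survival) restricted to survival > max(0, min_survival).

        Log-space fits exclude not only zero-survival points but, by
        default, grid points supported by fewer than ~10 surviving
        events: between rare tail order statistics the empirical
        survival is constant over long grid runs, and those nearly
        information-free points would otherwise dominate an unweighted
        fit.
        """
        keep = self.survival > max(min_survival, 0.0)
        return self.times_s[keep], self.survival[keep]


@dataclass
class ExpMixtureFit:
    """Fitted survival model.

    ``alpha`` is the weight of the fast-dissociating component τ₁; for a
    one-component fit alpha is 1 and ``tau2_s`` is None.  ``ssr`` is the
    residual sum of squares in log₁₀-survival space over the
    ``n_points`` fitted grid points.
    """

    n_components: int
    alpha: float
    tau1_s: float
    tau2_s: Optional[float]
    ssr: float
    n_obs: int
    n_points: int
    sample_checksum: str = ""
    se_alpha: Optional[float] = None
    se_tau1: Optional[float] = None
    se_tau2: Optional[float] = None

    def model_survival(self, x):
        x = np.asarray(x, dtype=float)
        if self.n_components == 1:
            return np.exp(-x / self.tau1_s)
        return self.alpha * np.exp(-x / self.tau1_s) + (1.0 - self.alpha) * np.exp(
            -x / self.tau2_s
        )

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "alpha": self.alpha,
            "tau1_s": self.tau1_s,
            "tau2_s": self.tau2_s,
            "ssr_log10": self.ssr,
            "n_obs": self.n_obs,
            "n_points": self.n_points,
            "se_alpha": self.se_alpha,
            "se_tau1": self.se_tau1,
            "se_tau2": self.se_tau2,
        }


# ---------------------------------------------------------------------------
# operations


def compute_dwell_times(tracks: TrackSet) -> DwellSample:
    """Convert filtered trajectories to recorded dwell times.

    dwell = (observed frames − 1)·Δt per track.  Tracks seen in a single
    frame have no measurable dwell under this convention and must be
    filtered out beforehand (an :class:`InputError` is raised otherwise).
    """
    if len(tracks) == 0:
        raise InputError("empty track set")
    dt = tracks.acquisition.frame_interval_s
    n_obs = np.array([t.n_frames_observed for t in tracks])
    if np.any(n_obs < 2):
        raise InputError("1-frame tracks present: apply filter_tracks first")
    return DwellSample(durations_s=(n_obs - 1) * dt, frame_interval_s=dt)


def survival_curve(sample: DwellSample) -> SurvivalCurve:
    """Empirical survival (1−CDF) on the frame-interval grid.

    Evaluated at t = k·Δt from the minimum to one bin past the maximum
    recorded dwell; S(t) = #(durations ≥ t)/n, so S is 1 at the minimum
    dwell and 0 at the final grid point.
    """
    dt = sample.frame_interval_s
    d = sample.durations_s
    kmin = int(round(np.min(d) / dt))
    kmax = int(round(np.max(d) / dt))
    ks = np.arange(kmin, kmax + 2)
    times = ks * dt
    # durations are multiples of dt; count d >= t with half-bin guard
    surv = np.array([(d >= t - 0.5 * dt).sum() for t in times]) / sample.n
    return SurvivalCurve(times_s=times, survival=surv, n=sample.n)


def _fit_log10_survival(x, log10_s, n_components, starts):
    """Least-squares core shared by fit_survival's multistart loop."""

    def resid1(p):
        return -x / (p[0] * np.log(10.0)) - log10_s

    def resid2(p):
        a, t1, t2 = p
        m = a * np.exp(-x / t1) + (1.0 - a) * np.exp(-x / t2)
        return np.log10(np.maximum(m, 1e-300)) - log10_s

    best = None
    diagnostics = []
    for p0 in starts:
        try:
            if n_components == 1:
                res = optimize.least_squares(
                    resid1, [p0], bounds=([1e-6], [np.inf]), method="trf"
                )
            else:
                res = optimize.least_squares(
                    resid2,
                    list(p0),
                    bounds=([0.0, 1e-6, 1e-6], [1.0, np.inf, np.inf]),
                    method="trf",
                )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append((p0, repr(exc)))
            continue
        ssr = float(np.sum(res.fun**2))
        diagnostics.append((p0, ssr, res.success))
        if res.success and (best is None or ssr < best[1] - 1e-14):
            best = (res.x, ssr)
    if best is None:
        raise FitError("survival fit failed to converge", diagnostics)
    return best


def fit_survival_curve(
    curve: SurvivalCurve,
    n_components: int,
    min_x_s: float = 0.0,
    sample_checksum: str = "",
    min_survivors: int = 10,
) -> ExpMixtureFit:
    """Fit a survival curve (empirical or analytic) to the mixture model.

    Time is measured from the first nonzero-survival grid point.  Grid
    points supported by fewer than ``min_survivors`` events are excluded
    along with zero-survival points (see :meth:`SurvivalCurve.nonzero`);
    pass ``min_survivors=0`` to fit every positive point.  ``min_x_s``
    floors the τ₁ multistart guess (the frame interval, when fitting
    real samples).
    """
    if n_components not in (1, 2):
        raise ParameterError("n_components must be 1 or 2")
    cutoff = (min_survivors - 0.5) / curve.n if curve.n > 0 and min_survivors > 0 else 0.0
    t, s = curve.nonzero(cutoff)
    if n_components == 2 and t.size < 10:
        raise InputError("need >= 10 nonzero survival points for a 2-component fit")
    if t.size < 2:
        raise FitError("degenerate survival curve (fewer than 2 nonzero points)")
    x = t - t[0]
    log10_s = np.log10(s)

    # tau1 guess: first time at which survival < 1/e, measured from t[0]
    below = np.nonzero(s < np.exp(-1.0))[0]
    tau_guess = x[below[0]] if below.size else x[-1]
    tau_guess = max(tau_guess, min_x_s, 1e-6)

    if n_components == 1:
        starts = [scale * tau_guess for scale in (0.5, 1.0)]
        params, ssr = _fit_log10_survival(x, log10_s, 1, starts)
        return ExpMixtureFit(
            n_components=1,
            alpha=1.0,
            tau1_s=float(params[0]),
            tau2_s=None,
            ssr=ssr,
            n_obs=curve.n,
            n_points=int(t.size),
            sample_checksum=sample_checksum,
        )
    starts = [
        (a, scale * tau_guess, mult * scale * tau_guess)
        for scale in (0.25, 0.5, 1.0)
        for mult in (2.0, 5.0, 10.0)
        for a in (0.3, 0.7)
    ]
    params, ssr = _fit_log10_survival(x, log10_s, 2, starts)
    a, t1, t2 = params
    if t1 > t2:  # canonical ordering: tau1 <= tau2, alpha weights tau1
        t1, t2, a = t2, t1, 1.0 - a
    return ExpMixtureFit(
        n_components=2,
        alpha=float(a),
        tau1_s=float(t1),
        tau2_s=float(t2),
        ssr=ssr,
        n_obs=curve.n,
        n_points=int(t.size),
        sample_checksum=sample_checksum,
    )


def fit_survival(
    sample: DwellSample,
    n_components: int,
    n_bootstrap: int = 0,
    bootstrap_seed: int = 0,
) -> ExpMixtureFit:
    """Fit the survival curve to a one- or two-component exponential model.

    Nonlinear least squares of log₁₀(empirical survival) against the
    log₁₀ model on the Δt grid, zero-survival points excluded, time
    measured from the minimum recorded dwell.  Multistart: τ₁ is seeded
    from the first grid time at which survival drops below 1/e (scaled
    by 0.5 and 1), τ₂ ∈ {2, 5}·τ₁, α ∈ {0.3, 0.7}; the lowest-SSR
    converged start wins, ties broken by deterministic start order.

    Set ``n_bootstrap`` > 0 to attach seeded case-resampling bootstrap
    SDs to the returned parameters.
    """
    if np.allclose(sample.durations_s, sample.durations_s[0]):
        raise FitError("degenerate dwell sample (all durations equal)")
    curve = survival_curve(sample)
    fit = fit_survival_curve(
        curve,
        n_components,
        min_x_s=sample.frame_interval_s,
        sample_checksum=sample.checksum(),
    )
    fit.n_obs = sample.n

    if n_bootstrap > 0:
        rng = np.random.default_rng(bootstrap_seed)
        reps = []
        for _ in range(n_bootstrap):
            boot = DwellSample(
                durations_s=rng.choice(sample.durations_s, size=sample.n, replace=True),
                frame_interval_s=sample.frame_interval_s,
            )
            try:
                f = fit_survival(boot, n_components)
            except (FitError, InputError):
                continue
            reps.append((f.alpha, f.tau1_s, f.tau2_s if f.tau2_s is not None else np.nan))
        if len(reps) >= 10:
            arr = np.asarray(reps, dtype=float)
            fit.se_alpha = float(np.std(arr[:, 0], ddof=1))
            fit.se_tau1 = float(np.std(arr[:, 1], ddof=1))
            if n_components == 2:
                fit.se_tau2 = float(np.std(arr[:, 2], ddof=1))
    return fit


def select_dwell_model(fit1: ExpMixtureFit, fit2: ExpMixtureFit) -> ExpMixtureFit:
    """Choose between the one- and two-component survival fits.

    The two-component fit is returned iff the extra-sum-of-squares
    F-test (2 extra parameters) gives p < 0.01 AND the mixture is
    non-degenerate: α ∈ [0.01, 0.99] and τ₂/τ₁ ≥ 2.  The separation
    guard exists because the unweighted log-space SSR is dominated by
    the low-count tail, which makes the F statistic anti-conservative:
    pure single-exponential data can produce a nominally significant
    second component with τ₂/τ₁ ≈ 1.7, while genuinely resolvable
    mixtures sit at ratios well above 2.  Otherwise the
    single-exponential fit is kept.
    """
    if fit1.n_components != 1 or fit2.n_components != 2:
        raise InputError("expected (1-component, 2-component) fits in that order")
    if fit1.sample_checksum != fit2.sample_checksum or fit1.n_points != fit2.n_points:
        raise InputError("fits were not computed on the same sample")
    df2 = fit2.n_points - 3
    if df2 <= 0 or fit2.ssr <= 0:
        return fit1
    f_stat = ((fit1.ssr - fit2.ssr) / 2.0) / (fit2.ssr / df2)
    p = stats.f.sf(max(f_stat, 0.0), 2, df2)
    if p < 0.01 and 0.01 <= fit2.alpha <= 0.99 and fit2.tau2_s / fit2.tau1_s >= 2.0:
        return fit2
    return fit1


def mean_dwell(sample: DwellSample) -> float:
    """Arithmetic mean of the recorded dwell times.

    Condition-to-condition fold changes are ratios of these means (not
    ratios of fitted time constants).
    """
    return float(np.mean(sample.durations_s))


def model_mean(fit: ExpMixtureFit) -> float:
    """Mean dwell implied by the fitted mixture: α·τ₁ + (1−α)·τ₂."""
    if fit.n_components == 1:
        return float(fit.tau1_s)
    return float(fit.alpha * fit.tau1_s + (1.0 - fit.alpha) * fit.tau2_s)
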