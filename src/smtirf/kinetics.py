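"""Biosensor-trace kinetics: product densities, initial rates, kcat, synergy.

A lipid-binding biosensor reports product-lipid formation on a supported
bilayer as a bulk fluorescence time series.  Because sensor occupancy
stays far below saturation (<0.1% of product lipids bound), intensity is
taken as proportional to product density: the trace is normalized from
0 to 1 between a baseline and a plateau window, multiplied by the total
product density the plateau represents, and the initial rate is an
ordinary least-squares slope over the early window before substrate
depletion matters (product ≤ cap·total, default cap 0.1, ≲5% secant
bias under the first-order depletion law).  Dividing by the membrane
density of enzymes gives the per-enzyme catalytic rate

    kcat = initial rate / enzyme density      [lipids/s per enzyme],

which is invariant to the arbitrary intensity scale of the sensor.
Two-phase (ATP-spike) experiments compare conditions at measured enzyme
densities; the density-normalized activation fold is the ratio of
per-enzyme rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitError, InputError, ParameterError


@dataclass
class SensorTrace:
    """Bulk fluorescence time series (times in s, intensities in a.u.)."""

    times_s: np.ndarray
    intensities: np.ndarray
    normalized: bool = False
    clipped: bool = False

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.size != self.intensities.size:
            raise InputError("times/intensities length mismatch")
        if self.times_s.size < 2 or np.any(np.diff(self.times_s) <= 0):
            raise InputError("times must be strictly increasing with >= 2 points")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.times_s, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorTrace":
        df = pd.read_csv(path)
        cols = list(df.columns[:2])
        return cls(times_s=df[cols[0]].to_numpy(), intensities=df[cols[1]].to_numpy())


@dataclass
class ProductTrace:
    """Product lipid density over time, bounded by the total density."""

    times_s: np.ndarray
    product_density: np.ndarray      # lipids per µm²
    total_density: float             # lipids per µm²

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.product_density = np.asarray(self.product_density, dtype=float)
        if np.any(self.product_density < 0) or np.any(
            self.product_density > self.total_density * (1 + 1e-9)
        ):
            raise InputError("product density must lie in [0, total_density]")


@dataclass
class RateFit:
    """Initial-rate window diagnostics."""

    rate_per_um2_s: float
    t_start_s: float
    t_end_s: float
    n_points: int


@dataclass
class KineticsResult:
    initial_rate_per_um2_s: float
    enzyme_density_per_um2: float
    kcat_per_s: float
    window: Tuple[float, float]
    n_points: int

    def to_dict(self) -> dict:
        return {
            "initial_rate_per_um2_s": self.initial_rate_per_um2_s,
            "enzyme_density_per_um2": self.enzyme_density_per_um2,
            "kcat_per_s": self.kcat_per_s,
            "window_s": list(self.window),
            "n_points": self.n_points,
        }


# ---------------------------------------------------------------------------
# operations


def _window_mean(trace: SensorTrace, window: Tuple[float, float]) -> float:
    t0, t1 = window
    mask = (trace.times_s >= t0) & (trace.times_s <= t1)
    if not np.any(mask):
        raise InputError(f"window {window} contains no trace points")
    return float(np.mean(trace.intensities[mask]))


def normalize_sensor_trace(
    trace: SensorTrace,
    baseline_window: Tuple[float, float],
    plateau_window: Tuple[float, float],
) -> SensorTrace:
    """Normalize a sensor trace from 0 (baseline) to 1 (plateau).

    (I − baseline_mean)/(plateau_mean − baseline_mean), clipped to
    [0, 1.05]; clipping is flagged on the returned trace.  A plateau not
    above the baseline means the reaction did not complete and raises
    :class:`InputError`.
    """
    if baseline_window[1] > plateau_window[0] and plateau_window[1] > baseline_window[0]:
        raise InputError("baseline and plateau windows must not overlap")
    base = _window_mean(trace, baseline_window)
    plat = _window_mean(trace, plateau_window)
    if plat <= base:
        raise InputError("plateau mean <= baseline mean: reaction did not complete")
    norm = (trace.intensities - base) / (plat - base)
    clipped = bool(np.any(norm < 0) or np.any(norm > 1.05))
    norm = np.clip(norm, 0.0, 1.05)
    return SensorTrace(
        times_s=trace.times_s.copy(),
        intensities=norm,
        normalized=True,
        clipped=clipped,
    )


def trace_to_product_density(norm: SensorTrace, total_density: float) -> ProductTrace:
    """Scale a normalized trace to absolute product lipids per µm²."""
    if total_density < 0:
        raise ParameterError("total_density must be >= 0")
    if not norm.normalized and (norm.intensities.min() < 0 or norm.intensities.max() > 1.05):
        raise InputError("trace does not look normalized to [0, 1.05]")
    product = np.minimum(norm.intensities * total_density, total_density)
    return ProductTrace(
        times_s=norm.times_s.copy(),
        product_density=product,
        total_density=float(total_density),
    )


def initial_rate(product: ProductTrace, depletion_cap: float = 0.1) -> RateFit:
    """OLS slope of product density over the pre-depletion window.

    The window is the maximal prefix of the trace with product ≤
    cap·total (default cap 0.1).  With at least 5 points required; the
    slope of the depletion law P(t) = S₀(1 − e^(−kcat·E·t/S₀)) over this
    window underestimates the true initial rate kcat·E by ~cap/2.
    """
    if not 0 < depletion_cap <= 1:
        raise ParameterError("depletion_cap must be in (0, 1]")
    thresh = depletion_cap * product.total_density
    below = product.product_density <= thresh + 1e-12
    # maximal prefix
    n_win = int(np.argmin(below)) if not below.all() else below.size
    if n_win < 5:
        raise FitError(
            "fewer than 5 points below the depletion cap; use a smaller cap "
            "or denser early sampling"
        )
    t = product.times_s[:n_win]
    p = product.product_density[:n_win]
    slope, _ = np.polyfit(t, p, 1)
    return RateFit(
        rate_per_um2_s=float(slope),
        t_start_s=float(t[0]),
        t_end_s=float(t[-1]),
        n_points=n_win,
    )


def compute_kcat(rate_per_um2_s: float, enzyme_density_per_um2: float) -> float:
    """Per-enzyme catalytic rate: initial rate divided by enzyme density."""
    if enzyme_density_per_um2 <= 0:
        raise ParameterError("enzyme_density must be > 0")
    return float(rate_per_um2_s / enzyme_density_per_um2)


def kcat_from_trace(
    trace: SensorTrace,
    baseline_window: Tuple[float, float],
    plateau_window: Tuple[float, float],
    total_density: float,
    enzyme_density: float,
    depletion_cap: float = 0.1,
) -> KineticsResult:
    """Full trace-to-kcat pipeline: normalize → convert → rate → kcat."""
    norm = normalize_sensor_trace(trace, baseline_window, plateau_window)
    product = trace_to_product_density(norm, total_density)
    rate = initial_rate(product, depletion_cap)
    return KineticsResult(
        initial_rate_per_um2_s=rate.rate_per_um2_s,
        enzyme_density_per_um2=enzyme_density,
        kcat_per_s=compute_kcat(rate.rate_per_um2_s, enzyme_density),
        window=(rate.t_start_s, rate.t_end_s),
        n_points=rate.n_points,
    )


def fit_adsorption(trace: SensorTrace) -> Tuple[float, float]:
    """Fit a pseudo-first-order membrane equilibration curve.

    Least squares of I(t) = plateau·(1 − e^(−k_obs·t)); returns
    (k_obs [1/s], plateau [a.u.]).  Raises FitError on non-convergence;
    a trace shorter than ~3/k_obs is accepted but less constrained.
    """
    t = trace.times_s
    y = trace.intensities
    if np.ptp(y) <= 0 or np.allclose(y, y[0]):
        raise FitError("degenerate trace: no equilibration signal")
    plat0 = float(np.max(y))
    # crude k guess from time to half-plateau
    half_idx = np.nonzero(y >= 0.5 * plat0)[0]
    k0 = np.log(2.0) / max(t[half_idx[0]], (t[1] - t[0])) if half_idx.size else 1.0 / t[-1]

    def model(tt, k, plat):
        return plat * (1.0 - np.exp(-k * tt))

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[k0, plat0], bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"adsorption fit failed: {exc}") from exc
    k_obs, plateau = float(popt[0]), float(popt[1])
    return k_obs, plateau


def synergy_fold(
    rate_test: float,
    rate_ref: float,
    density_test: float,
    density_ref: float,
) -> float:
    """Density-normalized activation fold between two conditions.

    fold = (rate_test/rate_ref) / (density_test/density_ref): the ratio
    of per-enzyme rates, removing the contribution of differential
    membrane localization from the activity comparison.
    """
    if min(rate_test, rate_ref, density_test, density_ref) <= 0:
        raise ParameterError("rates and densities must be > 0")
    return float((rate_test / rate_ref) / (density_test / density_ref))
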