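"""Independent reference estimators used only by the test suite.

These deliberately avoid the package's fitting code paths: the dwell
oracle maximizes the exact discretized-mixture likelihood on raw frame
counts, the diffusion oracle is an EM algorithm on unbinned step sizes,
and the initial-rate oracle is the closed-form OLS slope of the
depletion law.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def mle_dwell_mixture(durations_s, frame_interval_s):
    """Maximum-likelihood fit of the frame-discretized exponential mixture.

    Uses the exact probability mass of observing m+1 frames given the
    two-frame minimum: P(recorded = m·Δt | recorded ≥ Δt) =
    (S(mΔt) − S((m+1)Δt)) / S(Δt) with S the raw mixture survival.
    Grid multistart + Nelder-Mead refinement; canonical ordering.
    """
    dt = frame_interval_s
    m = np.round(np.asarray(durations_s) / dt).astype(int)
    vals, cnt = np.unique(m, return_counts=True)

    def nll(p):
        a, t1, t2 = p
        if not (0 <= a <= 1) or t1 <= 0 or t2 <= 0:
            return np.inf

        def S(k):
            return a * np.exp(-k * dt / t1) + (1 - a) * np.exp(-k * dt / t2)

        pm = (S(vals) - S(vals + 1)) / S(1)
        return -np.sum(cnt * np.log(np.maximum(pm, 1e-300)))

    mean_d = float(np.mean(durations_s))
    best = None
    for a0 in (0.3, 0.5, 0.7):
        for t10 in (0.3 * mean_d, 0.7 * mean_d):
            for mult in (3.0, 8.0):
                r = optimize.minimize(
                    nll,
                    [a0, t10, mult * t10],
                    method="Nelder-Mead",
                    options=dict(xatol=1e-7, fatol=1e-7, maxiter=8000),
                )
                if best is None or r.fun < best.fun:
                    best = r
    a, t1, t2 = best.x
    if t1 > t2:
        t1, t2, a = t2, t1, 1 - a
    return float(a), float(t1), float(t2)


def em_rayleigh_mixture(r_um, lag_s, n_iter=500, tol=1e-10):
    """EM maximum likelihood for a two-component Rayleigh mixture on raw steps.

    Component j has per-axis variance σ_j² = 2·D_j·τ; the Rayleigh MLE
    update is σ_j² = Σγ_ij r_i² / (2 Σγ_ij).  Returns (alpha, D1, D2)
    with D1 <= D2 and alpha the D1 weight.
    """
    r = np.asarray(r_um, dtype=float)
    r2 = r**2
    mean_s2 = np.mean(r2) / 2.0
    a, s1, s2 = 0.5, 0.5 * mean_s2, 2.0 * mean_s2
    prev = np.inf
    for _ in range(n_iter):
        p1 = a * r / s1 * np.exp(-r2 / (2 * s1))
        p2 = (1 - a) * r / s2 * np.exp(-r2 / (2 * s2))
        tot = np.maximum(p1 + p2, 1e-300)
        g = p1 / tot
        a = float(np.mean(g))
        s1 = float(np.sum(g * r2) / (2 * np.sum(g)))
        s2 = float(np.sum((1 - g) * r2) / (2 * np.sum(1 - g)))
        ll = float(np.sum(np.log(tot)))
        if abs(ll - prev) < tol:
            break
        prev = ll
    D1, D2 = s1 / (2 * lag_s), s2 / (2 * lag_s)
    if D1 > D2:
        D1, D2, a = D2, D1, 1 - a
    return float(a), float(D1), float(D2)


def ols_slope_of_depletion(t, rate0, total, cap):
    """Closed-form OLS slope of P(t)=total·(1−e^(−rate0·t/total)) on the
    discrete grid prefix with P <= cap·total (intercept free)."""
    t = np.asarray(t, dtype=float)
    p = total * (1.0 - np.exp(-rate0 * t / total))
    keep = p <= cap * total + 1e-12
    n = int(np.argmin(keep)) if not keep.all() else keep.size
    tt, pp = t[:n], p[:n]
    tbar, pbar = tt.mean(), pp.mean()
    return float(np.sum((tt - tbar) * (pp - pbar)) / np.sum((tt - tbar) ** 2))
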