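"""Seeded simulators for every input the analysis stages consume.

These forward models emulate the processes a single-molecule TIRF
experiment on a supported bilayer produces: Poisson arrivals of membrane
binders, two-population exponential dwell times discretized at the frame
interval, two-species 2-D Brownian diffusion, optional rebinding
("membrane hopping") and photobleaching, Gaussian-PSF spot movies with
shot and read noise, pseudo-first-order adsorption traces, and
substrate-depleting surface-catalysis traces with sensor noise.

Every function takes an explicit integer seed (or a config carrying
one); fixed seed ⇒ bit-identical output.  No global random state.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.special import erf

from .diffusion import StepSample
from .dwell import DwellSample
from .errors import ParameterError
from .kinetics import SensorTrace
from .params import (
    AcquisitionParams,
    BindingSimConfig,
    CatalysisSimConfig,
    ImagingParams,
)
from .tracks import Track, TrackSet


# ---------------------------------------------------------------------------
# dwell and step samples


def _draw_mixture_exponential(rng, n, alpha, tau1, tau2):
    taus = np.where(rng.random(n) < alpha, tau1, tau2 if tau2 is not None else tau1)
    return rng.exponential(taus)


def simulate_dwell_sample(
    n: int,
    alpha: float,
    tau1_s: float,
    tau2_s: Optional[float] = None,
    frame_interval_s: float = 0.052,
    min_frames: int = 2,
    seed: int = 0,
    redraw_below_min: bool = True,
) -> DwellSample:
    """Draw n recorded dwell times from a discretized exponential mixture.

    Raw dwells t are drawn from α·Exp(τ₁) + (1−α)·Exp(τ₂); a particle
    alive for t seconds is observed in floor(t/Δt)+1 frames, and the
    recorded dwell is (frames−1)·Δt.  Events shorter than ``min_frames``
    frames are redrawn (default, keeping the sample size at n) or
    dropped when ``redraw_below_min`` is False.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not 0 <= alpha <= 1:
        raise ParameterError("alpha must be in [0, 1]")
    if tau1_s <= 0 or (tau2_s is not None and tau2_s <= 0):
        raise ParameterError("time constants must be > 0")
    if frame_interval_s <= 0:
        raise ParameterError("frame_interval_s must be > 0")
    if min_frames < 0:
        raise ParameterError("min_frames must be >= 0")
    rng = np.random.default_rng(seed)
    dt = frame_interval_s

    def frames_of(t):
        return np.floor(t / dt).astype(int) + 1

    t = _draw_mixture_exponential(rng, n, alpha, tau1_s, tau2_s)
    frames = frames_of(t)
    if redraw_below_min:
        bad = frames < min_frames
        while np.any(bad):
            t_new = _draw_mixture_exponential(rng, int(bad.sum()), alpha, tau1_s, tau2_s)
            frames[bad] = frames_of(t_new)
            bad = frames < min_frames
    else:
        frames = frames[frames >= min_frames]
        if frames.size == 0:
            raise ParameterError("all draws below min_frames; nothing to record")
    return DwellSample(durations_s=(frames - 1) * dt, frame_interval_s=dt)


def simulate_step_sample(
    n_steps: int,
    alpha: float,
    D1_um2_s: float,
    D2_um2_s: Optional[float] = None,
    lag_s: float = 0.052,
    seed: int = 0,
) -> StepSample:
    """Draw frame-to-frame displacements from a Rayleigh diffusion mixture.

    Each step picks species D₁ with probability α (else D₂) and draws
    r ~ Rayleigh(σ) with σ² = 2Dτ, the step-size law of 2-D Brownian
    motion at lag τ.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    if not 0 <= alpha <= 1:
        raise ParameterError("alpha must be in [0, 1]")
    if D1_um2_s < 0 or (D2_um2_s is not None and D2_um2_s < 0):
        raise ParameterError("diffusion coefficients must be >= 0")
    rng = np.random.default_rng(seed)
    D = np.where(
        rng.random(n_steps) < alpha, D1_um2_s, D2_um2_s if D2_um2_s is not None else D1_um2_s
    )
    r = rng.rayleigh(np.sqrt(2.0 * D * lag_s))
    return StepSample(displacements_um=r, lag_s=lag_s)


# ---------------------------------------------------------------------------
# trajectory simulation


def simulate_track_set(config: BindingSimConfig, acq: AcquisitionParams) -> TrackSet:
    """Simulate membrane-binding trajectories.

    Particles arrive as a uniform Poisson process at
    arrival_rate·area per second over the acquisition, each drawing a
    dwell time (exponential mixture) and a diffusion coefficient
    (mixture; coupled to the dwell component when ``couple_states``).
    Positions evolve by 2-D Brownian steps with per-axis variance 2DΔt.
    Photobleaching (exponential hazard) truncates observation; on
    unbinding a particle may rebind within ``rebind_radius_um`` with
    probability ``rebind_prob``, continuing the same track.  A particle
    is recorded in frame k if it is membrane-bound at time k·Δt.
    """
    if acq.field_area_um2 is None or acq.field_area_um2 <= 0:
        raise ParameterError("acquisition field area must be > 0")
    rng = np.random.default_rng(config.seed)
    dt = acq.frame_interval_s
    T = acq.duration_s
    height, width = acq.field_size_um

    n_arrivals = rng.poisson(config.arrival_rate * acq.field_area_um2 * T)
    arrival_times = np.sort(rng.uniform(0.0, T, n_arrivals))

    tracks = []
    for tid, t_on in enumerate(arrival_times):
        x = rng.uniform(0.0, width)
        y = rng.uniform(0.0, height)
        # dwell component and diffusion species
        fast_dwell = rng.random() < config.dwell_alpha
        tau = config.dwell_tau1_s if fast_dwell else (config.dwell_tau2_s or config.dwell_tau1_s)
        if config.couple_states:
            slow_diff = fast_dwell
        else:
            slow_diff = rng.random() < config.diff_alpha
        D = config.D1_um2_s if slow_diff else (config.D2_um2_s or config.D1_um2_s)

        # binding event = chain of dwell segments separated by hops
        hop_times = []
        t_off = t_on + rng.exponential(tau)
        while config.rebind_prob > 0 and rng.random() < config.rebind_prob:
            hop_times.append(t_off)
            t_off += rng.exponential(tau)
        if config.bleach_rate_s > 0:
            t_off = min(t_off, t_on + rng.exponential(1.0 / config.bleach_rate_s))
        hop_times = [h for h in hop_times if h < t_off]

        k0 = int(math.ceil(t_on / dt))
        k1 = int(math.ceil(t_off / dt)) - 1  # last frame strictly before t_off
        k1 = min(k1, acq.n_frames - 1)
        if k1 < k0:
            continue
        n_obs = k1 - k0 + 1
        sd = math.sqrt(2.0 * D * dt)
        dxs = rng.normal(0.0, sd, n_obs - 1)
        dys = rng.normal(0.0, sd, n_obs - 1)
        # each hop between frames k and k+1 re-inserts the particle within
        # rebind_radius_um of its departure point
        for h in hop_times:
            k = int(math.floor(h / dt))
            idx = k - k0
            if 0 <= idx < n_obs - 1:
                ang = rng.uniform(0.0, 2.0 * math.pi)
                rad = config.rebind_radius_um * math.sqrt(rng.random())
                dxs[idx] += rad * math.cos(ang)
                dys[idx] += rad * math.sin(ang)
        xs = x + np.concatenate([[0.0], np.cumsum(dxs)])
        ys = y + np.concatenate([[0.0], np.cumsum(dys)])
        tracks.append(Track(track_id=tid, frames=np.arange(k0, k1 + 1), x=xs, y=ys))
    return TrackSet(tracks=tracks, acquisition=acq)


# ---------------------------------------------------------------------------
# movie rendering


def _integrated_gaussian_1d(centers_px, mu_px, sigma_px):
    """Pixel-integrated Gaussian profile (erf difference form)."""
    a = (centers_px - mu_px + 0.5) / (math.sqrt(2.0) * sigma_px)
    b = (centers_px - mu_px - 0.5) / (math.sqrt(2.0) * sigma_px)
    return 0.5 * (erf(a) - erf(b))


def render_movie(
    tracks: TrackSet, acq: AcquisitionParams, imaging: ImagingParams
) -> np.ndarray:
    """Render trajectories into a 16-bit TIFF-writable image stack.

    Per frame each live particle deposits a pixel-integrated 2-D
    Gaussian whose total intensity is Poisson(photons_per_particle);
    Poisson background and Gaussian read noise are added, and the frame
    is clipped to the uint16 range.  Out-of-bounds particles are clipped
    to the rendered window, not an error.
    """
    if imaging.psf_sigma_px <= 0:
        raise ParameterError("psf_sigma_px must be > 0")
    if acq.image_shape is None:
        raise ParameterError("acquisition must define image_shape for rendering")
    rows, cols = acq.image_shape
    px = acq.pixel_size_um
    rng = np.random.default_rng(imaging.seed)
    stack = np.zeros((acq.n_frames, rows, cols), dtype=float)

    half = int(math.ceil(6 * imaging.psf_sigma_px))
    for t in tracks:
        for f, xu, yu in zip(t.frames, t.x, t.y):
            if f >= acq.n_frames:
                continue
            cx = xu / px  # column, 0-based pixel centers
            cy = yu / px
            amp = rng.poisson(imaging.photons_per_particle)
            if amp == 0:
                continue
            c0, c1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
            r0, r1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
            c0c, c1c = max(c0, 0), min(c1, cols)
            r0c, r1c = max(r0, 0), min(r1, rows)
            if c0c >= c1c or r0c >= r1c:
                continue
            gx = _integrated_gaussian_1d(np.arange(c0c, c1c), cx, imaging.psf_sigma_px)
            gy = _integrated_gaussian_1d(np.arange(r0c, r1c), cy, imaging.psf_sigma_px)
            stack[f, r0c:r1c, c0c:c1c] += amp * np.outer(gy, gx)

    if imaging.background_photons > 0:
        stack += rng.poisson(imaging.background_photons, size=stack.shape)
    if imaging.read_noise_sd > 0:
        stack += rng.normal(0.0, imaging.read_noise_sd, size=stack.shape)
    return np.clip(np.round(stack), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# bulk traces


def simulate_catalysis_trace(config: CatalysisSimConfig) -> SensorTrace:
    """Simulate a substrate-depleting surface-catalysis sensor trace.

    P(t) = S₀·(1 − exp(−kcat·E·t/S₀)) (initial slope exactly kcat·E);
    the sensor reads P(t)/S₀ scaled to an arbitrary plateau with
    multiplicative Gaussian noise of fractional SD ``noise_sd_frac``.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.t_grid_s, dtype=float)
    S0 = config.substrate_density0
    rate0 = config.kcat_per_enzyme * config.enzyme_density
    if S0 <= 0 or rate0 == 0:
        frac = np.zeros_like(t)
    else:
        frac = 1.0 - np.exp(-rate0 * t / S0)
    intensity = config.plateau_au * frac
    if config.noise_sd_frac > 0:
        intensity = intensity * (1.0 + rng.normal(0.0, config.noise_sd_frac, t.size))
    return SensorTrace(times_s=t, intensities=intensity)


def simulate_adsorption_trace(
    k_obs: float,
    plateau: float,
    t_grid_s,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SensorTrace:
    """Pseudo-first-order membrane equilibration: I(t) = plateau·(1 − e^(−k·t))."""
    if k_obs < 0:
        raise ParameterError("k_obs must be >= 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(t_grid_s, dtype=float)
    y = plateau * (1.0 - np.exp(-k_obs * t))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, t.size)
    return SensorTrace(times_s=t, intensities=y)
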