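"""Acquisition and simulation parameter containers.

All physical quantities carry explicit units in their field names
(``_s`` seconds, ``_um`` micrometres, ``_um2_s`` µm²/s, ``per_um2``
molecules per µm²).  Every simulator takes one integer seed; no global
random state is used anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/acquisition geometry and timing.

    The frame interval doubles as the dwell-time bin width and the
    diffusion lag time: dwell survival curves are binned at it and
    step-size distributions are computed at a single-frame lag.

    Parameters
    ----------
    frame_interval_s:
        Seconds per frame (0.052 by default, i.e. 52 ms).
    pixel_size_um:
        Micrometres per pixel; only needed when an image geometry is set.
    image_shape:
        (rows, cols) in pixels, or None for track-table-only work.
    field_area_um2:
        Observed membrane area.  When ``image_shape`` is set this is
        derived as rows·cols·pixel_size_um² and must not disagree.
    n_frames:
        Number of frames in the acquisition.
    """

    frame_interval_s: float = 0.052
    pixel_size_um: float = 0.16
    image_shape: Optional[Tuple[int, int]] = None
    field_area_um2: Optional[float] = None
    n_frames: int = 1000

    def __post_init__(self):
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be > 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.image_shape is not None:
            rows, cols = self.image_shape
            if rows < 1 or cols < 1:
                raise ParameterError("image_shape entries must be >= 1")
            if self.pixel_size_um <= 0:
                raise ParameterError("pixel_size_um must be > 0")
            derived = rows * cols * self.pixel_size_um**2
            if self.field_area_um2 is None:
                object.__setattr__(self, "field_area_um2", derived)
            elif not np.isclose(self.field_area_um2, derived, rtol=1e-6):
                raise ParameterError(
                    "field_area_um2 inconsistent with image_shape × pixel_size_um²"
                )

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def field_size_um(self) -> Tuple[float, float]:
        """(height, width) of the field in µm."""
        if self.image_shape is not None:
            r, c = self.image_shape
            return (r * self.pixel_size_um, c * self.pixel_size_um)
        if self.field_area_um2 is None:
            raise ParameterError("no field geometry set")
        side = float(np.sqrt(self.field_area_um2))
        return (side, side)


@dataclass(frozen=True)
class BindingSimConfig:
    """Ground truth for the membrane-binding forward model.

    Particles arrive as a spatially uniform Poisson process, draw a
    dwell time from a two-component exponential mixture
    (weight ``dwell_alpha`` on the fast constant ``dwell_tau1_s``) and a
    diffusion coefficient from a two-species mixture (weight
    ``diff_alpha`` on the slow species ``D1_um2_s``).  The two draws are
    independent unless ``couple_states`` is set, in which case dwell
    component i forces diffusion component i.  ``rebind_prob`` /
    ``rebind_radius_um`` give a minimal membrane-hopping model (off by
    default); ``bleach_rate_s`` adds an exponential photobleaching
    hazard that truncates observation without ending the binding event.
    """

    arrival_rate: float = 0.05          # new particles per µm² per s
    dwell_alpha: float = 1.0
    dwell_tau1_s: float = 1.0
    dwell_tau2_s: Optional[float] = None
    diff_alpha: float = 1.0
    D1_um2_s: float = 0.5
    D2_um2_s: Optional[float] = None
    couple_states: bool = False
    rebind_prob: float = 0.0
    rebind_radius_um: float = 0.1
    bleach_rate_s: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("dwell_alpha", "diff_alpha", "rebind_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.arrival_rate < 0 or self.bleach_rate_s < 0:
            raise ParameterError("rates must be >= 0")
        if self.dwell_tau1_s <= 0:
            raise ParameterError("dwell_tau1_s must be > 0")
        if self.dwell_tau2_s is not None and self.dwell_tau2_s < self.dwell_tau1_s:
            raise ParameterError("require tau1 <= tau2")
        if self.D1_um2_s < 0:
            raise ParameterError("D1_um2_s must be >= 0")
        if self.D2_um2_s is not None and self.D2_um2_s < self.D1_um2_s:
            raise ParameterError("require D1 <= D2")
        if self.rebind_radius_um < 0:
            raise ParameterError("rebind_radius_um must be >= 0")


@dataclass(frozen=True)
class ImagingParams:
    """Rendering model for synthetic movies.

    Each particle contributes a 2-D Gaussian point-spread function whose
    integrated intensity is Poisson-distributed around
    ``photons_per_particle``; a Poisson background and additive Gaussian
    read noise complete the (idealized, gain-free) camera model.
    """

    psf_sigma_px: float = 1.2
    photons_per_particle: float = 300.0
    background_photons: float = 10.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.psf_sigma_px <= 0:
            raise ParameterError("psf_sigma_px must be > 0")
        if self.photons_per_particle < 0 or self.background_photons < 0:
            raise ParameterError("photon means must be >= 0")
        if self.read_noise_sd < 0:
            raise ParameterError("read_noise_sd must be >= 0")


@dataclass(frozen=True)
class CatalysisSimConfig:
    """Ground truth for substrate-depleting surface catalysis traces.

    Product lipids accumulate as P(t) = S₀·(1 − exp(−kcat·E·t/S₀)), the
    first-order depletion law whose initial slope is exactly kcat·E.
    The biosensor reports P(t)/S₀ scaled to an arbitrary plateau with
    multiplicative Gaussian noise.
    """

    kcat_per_enzyme: float = 57.0       # product lipids / s / enzyme
    enzyme_density: float = 0.2         # enzymes per µm²
    substrate_density0: float = 2.8e4   # substrate lipids per µm²
    t_grid_s: Sequence[float] = field(default_factory=lambda: tuple(np.arange(0.0, 1200.0, 2.0)))
    noise_sd_frac: float = 0.02
    plateau_au: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.kcat_per_enzyme, self.enzyme_density, self.substrate_density0) < 0:
            raise ParameterError("densities and rates must be >= 0")
        if self.noise_sd_frac < 0:
            raise ParameterError("noise_sd_frac must be >= 0")
        t = np.asarray(self.t_grid_s, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ParameterError("t_grid_s must be strictly increasing with >= 2 points")
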