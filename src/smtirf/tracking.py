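"""Spot detection and trajectory linking.

Detection uses a scale-normalized Laplacian-of-Gaussian response per
frame with sub-pixel localization by quadratic interpolation of the
response peak.  Linking replaces a full LAP tracker with gated
per-frame optimal bipartite assignment (Hungarian, squared-displacement
cost) plus optional simple gap closing — in the sparse single-molecule
regime merges and splits are negligible and the assignment cost matches
the LAP linking term.  Filtering applies the standard cleanup: drop
tracks present at the start or end of the movie (censored dwells),
tracks shorter than the minimum frame count, and optionally tracks with
excessive total displacement or positions inside an edge margin.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .errors import InputError, ParameterError
from .params import AcquisitionParams
from .tracks import FilterRules, Spot, Track, TrackSet


def _quadratic_subpixel(resp: np.ndarray, r: int, c: int):
    """1-D parabola offsets along each axis around an interior maximum."""

    def offset(vm, v0, vp):
        denom = vm - 2.0 * v0 + vp
        if denom >= 0:  # not a maximum along this axis
            return 0.0
        return float(0.5 * (vm - vp) / denom)

    dr = dc = 0.0
    if 0 < r < resp.shape[0] - 1:
        dr = offset(resp[r - 1, c], resp[r, c], resp[r + 1, c])
    if 0 < c < resp.shape[1] - 1:
        dc = offset(resp[r, c - 1], resp[r, c], resp[r, c + 1])
    return np.clip(dr, -0.5, 0.5), np.clip(dc, -0.5, 0.5)


def detect_spots(
    stack: np.ndarray,
    acq: AcquisitionParams,
    sigma_px: float,
    quality_threshold: float,
) -> Dict[int, List[Spot]]:
    """Detect diffraction-limited spots in every frame of an image stack.

    The response is −σ²·LoG(frame), so isolated Gaussian blobs of scale
    ≈ σ give positive peaks; local maxima above ``quality_threshold``
    are reported with sub-pixel positions (quadratic interpolation)
    converted to µm.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise InputError("stack must be a non-empty (frames, rows, cols) array")
    if sigma_px <= 0:
        raise ParameterError("sigma_px must be > 0")
    px = acq.pixel_size_um
    spots_by_frame: Dict[int, List[Spot]] = {}
    for f in range(stack.shape[0]):
        resp = -(sigma_px**2) * ndimage.gaussian_laplace(stack[f], sigma_px)
        peaks = peak_local_max(
            resp,
            min_distance=max(1, int(round(sigma_px))),
            threshold_abs=quality_threshold,
            exclude_border=False,
        )
        frame_spots = []
        for r, c in peaks:
            dr, dc = _quadratic_subpixel(resp, r, c)
            frame_spots.append(
                Spot(
                    frame=f,
                    x=(c + dc) * px,
                    y=(r + dr) * px,
                    intensity=float(stack[f, r, c]),
                    quality=float(resp[r, c]),
                )
            )
        # deterministic order: by (row, col) of the integer peak
        spots_by_frame[f] = frame_spots
    return spots_by_frame


def link_spots(
    spots_by_frame: Dict[int, List[Spot]],
    acq: AcquisitionParams,
    max_displacement_um: float,
    max_gap_frames: int = 0,
) -> TrackSet:
    """Link detected spots into trajectories.

    For each consecutive frame pair a minimum-total-squared-displacement
    bipartite assignment is solved among candidate pairs within the gate
    ``max_displacement_um``; unmatched spots start new tracks.  With
    ``max_gap_frames`` > 0, a track whose particle is missed for up to
    that many frames may be continued (gate scaled by the gap length);
    the gap frames are simply absent from the track.
    """
    if max_displacement_um <= 0:
        raise ParameterError("max_displacement_um must be > 0")
    if max_gap_frames < 0:
        raise ParameterError("max_gap_frames must be >= 0")
    frames = sorted(spots_by_frame)
    # active track state: list of [track_id, last_frame, last_x, last_y, spots]
    active: List[list] = []
    done: List[list] = []
    next_id = 0
    for f in frames:
        spots = spots_by_frame[f]
        # retire tracks that can no longer be continued
        still = []
        for tr in active:
            if f - tr[1] > max_gap_frames + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still

        assigned_spots = set()
        assigned_tracks = set()
        if active and spots:
            big = 1e12
            cost = np.full((len(active), len(spots)), big)
            for i, tr in enumerate(active):
                gap = f - tr[1]  # 1 for consecutive frames
                gate2 = (max_displacement_um**2) * gap
                for j, s in enumerate(spots):
                    d2 = (s.x - tr[2]) ** 2 + (s.y - tr[3]) ** 2
                    if d2 <= gate2:
                        cost[i, j] = d2
            rows, cols = optimize.linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < big:
                    tr = active[i]
                    s = spots[j]
                    tr[1] = f
                    tr[2], tr[3] = s.x, s.y
                    tr[4].append(s)
                    assigned_tracks.add(i)
                    assigned_spots.add(j)
        for j, s in enumerate(spots):
            if j not in assigned_spots:
                active.append([next_id, f, s.x, s.y, [s]])
                next_id += 1
    done.extend(active)
    done.sort(key=lambda tr: tr[0])
    tracks = [
        Track(
            track_id=tr[0],
            frames=np.array([s.frame for s in tr[4]]),
            x=np.array([s.x for s in tr[4]]),
            y=np.array([s.y for s in tr[4]]),
        )
        for tr in done
    ]
    return TrackSet(tracks=tracks, acquisition=acq)


def filter_tracks(tracks: TrackSet, rules: FilterRules) -> TrackSet:
    """Apply the trajectory cleanup rules; returns a new TrackSet.

    Removes tracks alive in the first movie frame, alive in the last,
    observed in fewer than ``min_frames`` frames, with total displacement
    above ``max_displacement_um`` (when set), or entering the field edge
    margin (when set).  Idempotent; the input is untouched.
    """
    acq = tracks.acquisition
    first_frame = 0
    last_frame = acq.n_frames - 1
    height, width = (np.inf, np.inf)
    if rules.edge_margin_um is not None:
        height, width = acq.field_size_um
    kept = []
    for t in tracks:
        if rules.drop_present_at_start and t.frames[0] <= first_frame:
            continue
        if rules.drop_present_at_end and t.frames[-1] >= last_frame:
            continue
        if t.n_frames_observed < rules.min_frames:
            continue
        if (
            rules.max_displacement_um is not None
            and t.total_displacement_um > rules.max_displacement_um
        ):
            continue
        if rules.edge_margin_um is not None:
            m = rules.edge_margin_um
            if (
                t.x.min() < m
                or t.y.min() < m
                or t.x.max() > width - m
                or t.y.max() > height - m
            ):
                continue
        kept.append(t)
    return TrackSet(tracks=kept, acquisition=acq)
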