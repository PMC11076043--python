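"""Spot detection, linking, filtering, and the movie round trip."""

import numpy as np
import pytest

from smtirf import (
    AcquisitionParams,
    BindingSimConfig,
    FilterRules,
    ImagingParams,
    InputError,
    Spot,
    Track,
    TrackSet,
    compute_dwell_times,
    compute_steps,
    detect_spots,
    filter_tracks,
    fit_survival,
    link_spots,
    render_movie,
    simulate_track_set,
    summarize_mobility,
)

DT = 0.052


def _spots(frame, positions):
    return [Spot(frame=frame, x=x, y=y) for x, y in positions]


class TestDetectSpots:
    def test_blank_frames_give_no_spots(self, acq_imaging):
        stack = np.zeros((3, 64, 64), dtype=np.uint16)
        spots = detect_spots(stack, acq_imaging, sigma_px=1.2, quality_threshold=1.0)
        assert all(len(v) == 0 for v in spots.values())

    def test_subpixel_localization_of_rendered_spot(self, acq_imaging):
        px = acq_imaging.pixel_size_um
        tr = Track(track_id=0, frames=[0], x=[20.3 * px], y=[31.7 * px])
        stack = render_movie(
            TrackSet(tracks=[tr], acquisition=acq_imaging),
            acq_imaging,
            ImagingParams(psf_sigma_px=1.5, photons_per_particle=1e5,
                          background_photons=0.0, read_noise_sd=0.0, seed=1),
        )
        spots = detect_spots(stack, acq_imaging, sigma_px=1.5, quality_threshold=10.0)
        assert len(spots[0]) == 1
        s = spots[0][0]
        assert abs(s.x / px - 20.3) < 0.1
        assert abs(s.y / px - 31.7) < 0.1

    def test_two_well_separated_spots(self, acq_imaging):
        px = acq_imaging.pixel_size_um
        tracks = [
            Track(track_id=0, frames=[0], x=[15.0 * px], y=[15.0 * px]),
            Track(track_id=1, frames=[0], x=[45.0 * px], y=[45.0 * px]),  # 30 px = 20 sigma apart
        ]
        stack = render_movie(
            TrackSet(tracks=tracks, acquisition=acq_imaging),
            acq_imaging,
            ImagingParams(psf_sigma_px=1.5, photons_per_particle=1e5,
                          background_photons=0.0, read_noise_sd=0.0, seed=2),
        )
        spots = detect_spots(stack, acq_imaging, sigma_px=1.5, quality_threshold=10.0)
        assert len(spots[0]) == 2

    def test_empty_stack_rejected(self, acq_imaging):
        with pytest.raises(InputError):
            detect_spots(np.zeros((0, 4, 4)), acq_imaging, 1.0, 1.0)


class TestLinkSpots:
    def test_two_stationary_spots_over_ten_frames(self, acq_imaging):
        by_frame = {f: _spots(f, [(1.0, 1.0), (5.0, 5.0)]) for f in range(10)}
        ts = link_spots(by_frame, acq_imaging, max_displacement_um=0.5)
        assert len(ts) == 2
        assert all(len(t) == 10 for t in ts)

    def test_moving_spot_within_gate_stays_one_track(self, acq_imaging):
        by_frame = {f: _spots(f, [(0.2 * f, 0.0)]) for f in range(10)}
        ts = link_spots(by_frame, acq_imaging, max_displacement_um=0.5)
        assert len(ts) == 1 and len(ts.tracks[0]) == 10

    def test_gate_breaks_large_jumps(self, acq_imaging):
        by_frame = {0: _spots(0, [(0.0, 0.0)]), 1: _spots(1, [(3.0, 0.0)])}
        ts = link_spots(by_frame, acq_imaging, max_displacement_um=0.5)
        assert len(ts) == 2

    def test_no_double_assignment_within_frame(self, acq_imaging):
        rng = np.random.default_rng(0)
        by_frame = {
            f: _spots(f, [(rng.uniform(0, 10), rng.uniform(0, 10)) for _ in range(8)])
            for f in range(15)
        }
        ts = link_spots(by_frame, acq_imaging, max_displacement_um=2.0)
        for t in ts:
            assert len(np.unique(t.frames)) == len(t.frames)

    def test_gap_closing(self, acq_imaging):
        frames = [0, 1, 3, 4]  # frame 2 missed
        by_frame = {f: _spots(f, [(1.0, 1.0)]) for f in frames}
        ts = link_spots(by_frame, acq_imaging, max_displacement_um=0.5, max_gap_frames=1)
        assert len(ts) == 1
        assert list(ts.tracks[0].frames) == frames


class TestFilterTracks:
    def _set(self, tracks, n_frames=100):
        acq = AcquisitionParams(frame_interval_s=DT, field_area_um2=100.0, n_frames=n_frames)
        return TrackSet(tracks=tracks, acquisition=acq)

    def test_removes_start_end_and_short_tracks(self):
        mk = lambda i, fr: Track(track_id=i, frames=fr, x=np.ones(len(fr)), y=np.ones(len(fr)))
        ts = self._set(
            [
                mk(0, range(0, 6)),      # present at movie start
                mk(1, range(95, 100)),   # present at movie end
                mk(2, [50]),             # 1-frame
                mk(3, range(40, 50)),    # passes
            ]
        )
        out = filter_tracks(ts, FilterRules())
        assert [t.track_id for t in out] == [3]

    def test_identity_on_all_passing_set(self):
        mk = lambda i, fr: Track(track_id=i, frames=fr, x=np.ones(len(fr)), y=np.ones(len(fr)))
        ts = self._set([mk(0, range(10, 20)), mk(1, range(30, 44))])
        out = filter_tracks(ts, FilterRules())
        assert [t.track_id for t in out] == [0, 1]
        assert len(ts) == 2  # input untouched

    def test_idempotent(self):
        mk = lambda i, fr: Track(track_id=i, frames=fr, x=np.ones(len(fr)), y=np.ones(len(fr)))
        ts = self._set([mk(0, range(0, 6)), mk(1, range(10, 20))])
        once = filter_tracks(ts, FilterRules())
        twice = filter_tracks(once, FilterRules())
        assert [t.track_id for t in twice] == [t.track_id for t in once]

    def test_displacement_and_edge_rules(self):
        far = Track(track_id=0, frames=[10, 11], x=[1.0, 9.0], y=[5.0, 5.0])
        edge = Track(track_id=1, frames=[10, 11], x=[0.1, 0.2], y=[5.0, 5.0])
        ok = Track(track_id=2, frames=[10, 11], x=[5.0, 5.2], y=[5.0, 5.0])
        ts = self._set([far, edge, ok])
        out = filter_tracks(
            ts, FilterRules(max_displacement_um=2.0, edge_margin_um=0.5)
        )
        assert [t.track_id for t in out] == [2]


class TestRoundTrip:
    def test_simulate_render_detect_link_recovers_constants(self):
        """End-to-end: ≥95% of tracks recovered and dwell/diffusion constants
        within 25% at SNR ≈ 5 and sparse density."""
        acq = AcquisitionParams(
            frame_interval_s=DT, pixel_size_um=0.16, image_shape=(96, 96), n_frames=400
        )
        tau_true, d_true = 0.4, 0.3
        cfg = BindingSimConfig(
            arrival_rate=0.08, dwell_alpha=1.0, dwell_tau1_s=tau_true,
            diff_alpha=1.0, D1_um2_s=d_true, seed=7,
        )
        ts = simulate_track_set(cfg, acq)
        gt = filter_tracks(ts, FilterRules())
        stack = render_movie(
            ts, acq,
            ImagingParams(psf_sigma_px=1.2, photons_per_particle=400,
                          background_photons=20, read_noise_sd=2, seed=8),
        )
        spots = detect_spots(stack, acq, sigma_px=1.2, quality_threshold=10.0)
        linked = link_spots(spots, acq, max_displacement_um=0.6, max_gap_frames=1)
        rec = filter_tracks(linked, FilterRules())

        # position-matched track recovery (within 1 px in >= 2 frames)
        rec_index = {}
        for t in rec:
            for f, x, y in zip(t.frames, t.x, t.y):
                rec_index.setdefault(f, []).append((x, y, t.track_id))
        tol = acq.pixel_size_um
        matched = 0
        for t in gt:
            hits = {}
            for f, x, y in zip(t.frames, t.x, t.y):
                for rx, ry, rid in rec_index.get(f, []):
                    if (rx - x) ** 2 + (ry - y) ** 2 <= tol**2:
                        hits[rid] = hits.get(rid, 0) + 1
            if hits and max(hits.values()) >= 2:
                matched += 1
        assert matched / len(gt) >= 0.95

        fit = fit_survival(compute_dwell_times(rec), 1)
        assert fit.tau1_s == pytest.approx(tau_true, rel=0.25)
        mob = summarize_mobility(compute_steps(rec))
        assert mob["mean_r2_um2"] / (4 * DT) == pytest.approx(d_true, rel=0.25)


class TestTrackCsvIO:
    def test_roundtrip(self, tmp_path, acq_52ms):
        cfg = BindingSimConfig(arrival_rate=0.01, seed=2)
        ts = simulate_track_set(cfg, acq_52ms)
        path = tmp_path / "tracks.csv"
        ts.to_csv(path)
        back = TrackSet.from_csv(path, acquisition=acq_52ms)
        assert len(back) == len(ts)
        assert np.allclose(back.tracks[0].x, ts.tracks[0].x)
        header = path.read_text().splitlines()[0]
        assert header == "TRACK_ID,FRAME,POSITION_X,POSITION_Y"
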