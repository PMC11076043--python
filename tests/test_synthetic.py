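"""Simulator correctness: closed forms, invariants, determinism."""

import numpy as np
import pytest
from scipy import stats

from smtirf import (
    AcquisitionParams,
    BindingSimConfig,
    CatalysisSimConfig,
    ImagingParams,
    ParameterError,
    compute_steps,
    render_movie,
    simulate_adsorption_trace,
    simulate_catalysis_trace,
    simulate_dwell_sample,
    simulate_step_sample,
    simulate_track_set,
)


class TestDwellSample:
    def test_mean_matches_tau_in_continuum_limit(self):
        # alpha=1 pure exponential; tiny frame interval, no minimum
        s = simulate_dwell_sample(
            100_000, 1.0, 2.0, None, frame_interval_s=1e-4, min_frames=0, seed=1
        )
        assert np.mean(s.durations_s) == pytest.approx(2.0, rel=0.02)

    def test_degenerate_mixture_is_single_exponential(self):
        # tau1 == tau2: KS against the analytic Exp(1) CDF
        s = simulate_dwell_sample(
            10_000, 0.5, 1.0, 1.0, frame_interval_s=1e-4, min_frames=0, seed=2
        )
        _, p = stats.kstest(s.durations_s, "expon", args=(0, 1.0))
        assert p > 0.01

    def test_empirical_survival_converges_to_mixture(self):
        n = 40_000
        alpha, t1, t2 = 0.6, 0.5, 2.0
        s = simulate_dwell_sample(n, alpha, t1, t2, frame_interval_s=1e-4, min_frames=0, seed=3)
        grid = np.linspace(0.0, 8.0, 400)
        emp = np.array([(s.durations_s >= g).mean() for g in grid])
        model = alpha * np.exp(-grid / t1) + (1 - alpha) * np.exp(-grid / t2)
        assert np.max(np.abs(emp - model)) < 3.0 / np.sqrt(n)

    def test_discretization_and_minimum(self):
        s = simulate_dwell_sample(5000, 0.5, 0.4, 1.5, 0.052, min_frames=2, seed=4)
        assert s.n == 5000
        # durations are positive multiples of dt, all >= dt (2-frame minimum)
        k = s.durations_s / 0.052
        assert np.allclose(k, np.round(k))
        assert s.durations_s.min() >= 0.052 - 1e-12

    def test_drop_mode_returns_fewer(self):
        s = simulate_dwell_sample(
            5000, 1.0, 0.1, None, 0.052, min_frames=2, seed=5, redraw_below_min=False
        )
        assert s.n < 5000

    def test_deterministic_for_fixed_seed(self):
        a = simulate_dwell_sample(100, 0.5, 0.5, 2.0, 0.052, seed=7)
        b = simulate_dwell_sample(100, 0.5, 0.5, 2.0, 0.052, seed=7)
        assert np.array_equal(a.durations_s, b.durations_s)

    @pytest.mark.parametrize("bad", [dict(alpha=1.5), dict(tau1_s=-1.0), dict(n=0)])
    def test_parameter_validation(self, bad):
        kwargs = dict(n=10, alpha=0.5, tau1_s=1.0, tau2_s=2.0)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            simulate_dwell_sample(**kwargs)


class TestStepSample:
    def test_single_species_rayleigh_gof(self):
        st = simulate_step_sample(20_000, 1.0, 0.5, None, 0.052, seed=1)
        sigma = np.sqrt(2 * 0.5 * 0.052)
        _, p = stats.kstest(st.displacements_um, "rayleigh", args=(0, sigma))
        assert p > 0.01

    def test_mean_square_step(self):
        st = simulate_step_sample(50_000, 1.0, 1.0, None, 0.052, seed=2)
        # E[r^2] = 4 D tau, SE of mean r^2 = sqrt(var)/sqrt(n); var(r^2)=16 D^2 tau^2
        expect = 4 * 1.0 * 0.052
        se = 4 * 1.0 * 0.052 / np.sqrt(st.n_steps)
        assert abs(np.mean(st.displacements_um**2) - expect) < 3 * se


class TestTrackSet:
    def test_zero_arrival_rate_gives_empty_set(self, acq_52ms):
        ts = simulate_track_set(BindingSimConfig(arrival_rate=0.0, seed=1), acq_52ms)
        assert len(ts) == 0

    def test_msd_of_brownian_steps(self, acq_52ms):
        cfg = BindingSimConfig(
            arrival_rate=0.02, dwell_alpha=1.0, dwell_tau1_s=1.0,
            diff_alpha=1.0, D1_um2_s=1.0, seed=3,
        )
        steps = compute_steps(simulate_track_set(cfg, acq_52ms))
        r2 = steps.displacements_um**2
        expect = 4 * 1.0 * 0.052
        assert np.mean(r2) == pytest.approx(expect, abs=3 * np.std(r2) / np.sqrt(r2.size))

    def test_deterministic_and_unique_ids(self, acq_52ms):
        cfg = BindingSimConfig(arrival_rate=0.02, seed=11)
        a = simulate_track_set(cfg, acq_52ms)
        b = simulate_track_set(cfg, acq_52ms)
        assert len(a) == len(b)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x, tb.x) and np.array_equal(ta.frames, tb.frames)

    def test_zero_field_area_rejected(self):
        acq = AcquisitionParams(field_area_um2=0.0, n_frames=10)
        with pytest.raises(ParameterError):
            simulate_track_set(BindingSimConfig(seed=1), acq)


class TestRenderMovie:
    def test_empty_trackset_is_pure_noise(self, acq_imaging):
        from smtirf import TrackSet

        stack = render_movie(
            TrackSet(tracks=[], acquisition=acq_imaging),
            acq_imaging,
            ImagingParams(background_photons=25.0, read_noise_sd=0.0, seed=1),
        )
        assert stack.dtype == np.uint16
        assert stack.mean() == pytest.approx(25.0, rel=0.05)

    def test_noiseless_centroid_matches_position(self, acq_imaging):
        from smtirf import Track, TrackSet

        px = acq_imaging.pixel_size_um
        x_px, y_px = 20.3, 31.7
        tr = Track(track_id=0, frames=[0], x=[x_px * px], y=[y_px * px])
        imaging = ImagingParams(
            psf_sigma_px=1.5, photons_per_particle=1e6,
            background_photons=0.0, read_noise_sd=0.0, seed=2,
        )
        stack = render_movie(TrackSet(tracks=[tr], acquisition=acq_imaging), acq_imaging, imaging)
        frame = stack[0].astype(float)
        yy, xx = np.mgrid[: frame.shape[0], : frame.shape[1]]
        cx = (frame * xx).sum() / frame.sum()
        cy = (frame * yy).sum() / frame.sum()
        # uint16 rounding limits agreement, not the Gaussian sampling itself
        assert abs(cx - x_px) < 1e-3 and abs(cy - y_px) < 1e-3

    def test_psf_validation(self, acq_imaging):
        with pytest.raises(ParameterError):
            ImagingParams(psf_sigma_px=0.0)


class TestCatalysisTrace:
    def test_zero_kcat_is_flat(self):
        cfg = CatalysisSimConfig(kcat_per_enzyme=0.0, noise_sd_frac=0.0, seed=1)
        tr = simulate_catalysis_trace(cfg)
        assert np.allclose(tr.intensities, 0.0)

    def test_initial_slope_is_kcat_times_density(self):
        # kcat=57, E=0.2, S0=2.8e4: d/dt P at t=0 is 11.4 lipids/µm²/s
        t = np.linspace(0.0, 1.0, 101)
        cfg = CatalysisSimConfig(
            kcat_per_enzyme=57.0, enzyme_density=0.2, substrate_density0=2.8e4,
            t_grid_s=tuple(t), noise_sd_frac=0.0, seed=1,
        )
        tr = simulate_catalysis_trace(cfg)
        product = tr.intensities * 2.8e4  # plateau_au=1 => intensity = P/S0
        slope0 = (product[1] - product[0]) / (t[1] - t[0])
        assert slope0 == pytest.approx(11.4, rel=1e-4)

    def test_substrate_conservation(self):
        for seed in range(5):
            cfg = CatalysisSimConfig(
                kcat_per_enzyme=500.0, t_grid_s=tuple(np.linspace(0, 5000, 300)),
                noise_sd_frac=0.0, seed=seed,
            )
            tr = simulate_catalysis_trace(cfg)
            assert np.all(tr.intensities * cfg.substrate_density0 <= cfg.substrate_density0 + 1e-9)


class TestAdsorptionTrace:
    def test_closed_form_value(self):
        tr = simulate_adsorption_trace(0.1, 1.0, np.linspace(0, 100, 1001), seed=1)
        i10 = np.interp(10.0, tr.times_s, tr.intensities)
        assert i10 == pytest.approx(1 - np.exp(-1), rel=1e-9)

    def test_fast_limit_steps_to_plateau(self):
        tr = simulate_adsorption_trace(1e6, 2.0, [0.0, 0.1, 0.2], seed=1)
        assert tr.intensities[1] == pytest.approx(2.0, rel=1e-6)

    def test_deterministic(self):
        a = simulate_adsorption_trace(0.05, 1.0, np.arange(0.0, 60, 0.5), noise_sd=0.02, seed=9)
        b = simulate_adsorption_trace(0.05, 1.0, np.arange(0.0, 60, 0.5), noise_sd=0.02, seed=9)
        assert np.array_equal(a.intensities, b.intensities)
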