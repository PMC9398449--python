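"""Photoconversion analysis chain and forward movie simulation."""

import numpy as np
import pytest

from kfibers import flux_balance as fb
from kfibers import kmt_simulator as ks
from kfibers import photoconversion as pc
from kfibers import synthetic_data as sd
from kfibers.nematic_field import Streamline
from kfibers.spindle_io import PhotoconversionMovie


def make_movie(frames, pixel_size=0.1, frame_interval=5.0, poles=None):
    T, H, W = frames.shape
    if poles is None:
        poles = np.array([[5.0, H / 2], [W - 5.0, H / 2]])
    tracks = np.broadcast_to(poles[None], (T, 2, 2)).copy()
    return PhotoconversionMovie(
        frames=frames, pixel_size=pixel_size, frame_interval=frame_interval,
        pole_tracks=tracks,
    )


class TestExtractLineProfile:
    def test_uniform_image_gives_flat_profile(self):
        movie = make_movie(np.full((1, 40, 80), 3.7))
        prof = pc.extract_line_profile(movie, 0)
        np.testing.assert_allclose(prof.intensity, 3.7, rtol=1e-12)

    def test_gaussian_stripe_peaks_at_its_position(self):
        H, W = 60, 100
        x = np.arange(W)
        img = np.exp(-((x - 42.0) ** 2) / (2 * 3.0**2))[None, :] * np.ones((H, 1))
        movie = make_movie(img[None])
        prof = pc.extract_line_profile(movie, 0)
        pk = pc.fit_peak(prof)
        # 42 px from image origin, pole at 5 px → 37 px = 3.7 µm
        assert pk.center_um == pytest.approx(3.7, abs=0.1)

    def test_band_average_rotation_invariant(self):
        """Rotating the frame and pole markers by 30° leaves the profile
        unchanged up to interpolation error."""
        from scipy import ndimage

        H, W = 120, 120
        x = np.arange(W)
        img = np.ones((H, 1)) * np.exp(-((x - 70.0) ** 2) / (2 * 4.0**2))[None, :]
        taper = np.exp(-((np.arange(H) - H / 2) ** 2) / (2 * 25.0**2))
        img = img * taper[:, None]
        poles = np.array([[20.0, 60.0], [100.0, 60.0]])
        m0 = make_movie(img[None], poles=poles)
        p0 = pc.extract_line_profile(m0, 0)

        ang = 30.0
        rot = ndimage.rotate(img, ang, reshape=False, order=3)
        c = np.array([W / 2, H / 2])
        th = np.radians(ang)
        R = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        poles_r = (poles - c) @ R.T + c
        m1 = make_movie(rot[None], poles=poles_r)
        p1 = pc.extract_line_profile(m1, 0)
        n = min(len(p0.intensity), len(p1.intensity))
        rms = np.sqrt(np.mean((p0.intensity[:n] - p1.intensity[:n]) ** 2))
        # bilinear band sampling + cubic image rotation: a few
        # percent of interpolation error is expected
        assert rms < 0.02 * p0.intensity.max()

    def test_pole_outside_frame_rejected(self):
        movie = make_movie(np.zeros((1, 20, 20)), poles=np.array([[-5.0, 10.0], [15.0, 10.0]]))
        with pytest.raises(ValueError):
            pc.extract_line_profile(movie, 0)


class TestFitPeak:
    def make_profile(self, centers_height, noise=0.0, seed=0, width=0.3):
        x = np.arange(0, 12, 0.1)
        y = np.zeros_like(x)
        for c, h in centers_height:
            y += h * np.exp(-((x - c) ** 2) / (2 * width**2))
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, y.shape)
        return pc.LineProfile(pos_um=x, intensity=y, frame=0)

    def test_exact_gaussian_recovered_to_machine_precision(self):
        prof = self.make_profile([(5.0, 2.0)])
        pk = pc.fit_peak(prof)
        assert pk.center_um == pytest.approx(5.0, abs=1e-8)
        assert pk.height == pytest.approx(2.0, rel=1e-6)

    def test_tie_break_prefers_previous_center(self):
        prof = self.make_profile([(3.0, 1.0), (8.0, 1.0)])
        left = pc.fit_peak(prof, previous_center=4.0)
        right = pc.fit_peak(prof, previous_center=7.0)
        assert left.center_um == pytest.approx(3.0, abs=0.05)
        assert right.center_um == pytest.approx(8.0, abs=0.05)

    def test_no_peak_above_noise_flagged(self):
        x = np.arange(0, 10, 0.1)
        prof = pc.LineProfile(pos_um=x, intensity=np.zeros_like(x), frame=0)
        pk = pc.fit_peak(prof)
        assert not pk.valid

    def test_center_error_small_at_moderate_snr(self):
        """Monte-Carlo: center recovered within 0.2 px at SNR 10."""
        errs = []
        for seed in range(500):
            # peak width comparable to the 5-px fit window: the regime the
            # window localizes well
            prof = self.make_profile([(5.0, 1.0)], noise=0.1, seed=seed, width=0.15)
            pk = pc.fit_peak(prof)
            if pk.valid:
                errs.append(abs(pk.center_um - 5.0))
        assert len(errs) > 450
        assert np.mean(errs) < 0.2 * 0.1  # 0.2 px at 0.1 µm/px


class TestCorrections:
    def test_no_background_no_bleach_identity(self):
        raw = np.array([3.0, 2.0, 1.0])
        np.testing.assert_array_equal(pc.correct_height(raw), raw)

    def test_pure_bleaching_restored(self):
        t = np.linspace(0, 2, 20)
        bleach = np.exp(-0.8 * t)
        raw = 5.0 * bleach
        out = pc.correct_height(raw, 0.0, bleach)
        np.testing.assert_allclose(out, 5.0, rtol=1e-9)

    def test_nonpositive_bleach_rejected(self):
        with pytest.raises(ValueError):
            pc.correct_height(np.ones(3), 0.0, np.array([1.0, 0.5, 0.0]))


class TestFitTurnover:
    def test_single_exponential_degenerates_gracefully(self):
        t = np.linspace(0, 5, 60)
        y = 2.0 * np.exp(-0.5 * t)
        fit = pc.fit_turnover(t, y)
        assert fit.valid
        # slow rate recovered; fast amplitude negligible
        assert fit.k_slow == pytest.approx(0.5, rel=0.05)
        assert fit.amp_fast < 0.05 * fit.amp_slow

    def test_paper_like_parameters_recovered(self):
        """Slow fraction 0.26, lifetimes 2.8/0.26 min at 5 s sampling."""
        t = np.arange(0, 2.5, 5 / 60)
        y = pc.dual_exponential(t, 0.26, 1 / 2.8, 0.74, 1 / 0.26)
        fit = pc.fit_turnover(t, y)
        assert fit.slow_fraction == pytest.approx(0.26, rel=0.05)
        assert fit.lifetime_slow_min == pytest.approx(2.8, rel=0.05)
        assert fit.lifetime_fast_min == pytest.approx(0.26, rel=0.05)

    def test_slow_fraction_estimator_unbiased(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 2.5, 5 / 60)
        truth = 0.3
        estimates = []
        for _ in range(200):
            y = pc.dual_exponential(t, truth, 1 / 2.8, 1 - truth, 1 / 0.26)
            y = y + rng.normal(0, 0.01, y.shape)
            fit = pc.fit_turnover(t, y)
            if fit.valid:
                estimates.append(fit.slow_fraction)
        est = np.array(estimates)
        sem = est.std() / np.sqrt(len(est))
        assert abs(est.mean() - truth) < max(2 * sem, 0.01)

    def test_too_few_points_flagged(self):
        fit = pc.fit_turnover(np.arange(5.0), np.ones(5))
        assert not fit.valid


class TestFitSpeed:
    def test_stationary_line_zero_speed(self):
        t = np.arange(10) * 5 / 60
        fit = pc.fit_speed(t, np.full(10, 3.0))
        assert fit.speed_um_per_min == pytest.approx(0.0, abs=1e-12)
        assert fit.initial_position_um == pytest.approx(3.0)

    def test_unit_conversion(self):
        """0.1 µm poleward per 5 s frame = 1.2 µm/min."""
        t = np.arange(12) * 5 / 60
        centers = 4.0 - 0.1 * np.arange(12)
        fit = pc.fit_speed(t, centers)
        assert fit.speed_um_per_min == pytest.approx(1.2)

    def test_too_few_frames_flagged(self):
        fit = pc.fit_speed(np.arange(3.0), np.arange(3.0))
        assert not fit.valid


def small_population(v_const=1.0, n_lines=6, s_kin=6.0):
    s = np.linspace(0, s_kin, 80)
    lines = [
        Streamline(
            points=np.stack([s, np.full_like(s, -1.0 + 0.4 * i)], axis=1), s=s, pole=0
        )
        for i in range(n_lines)
    ]
    snap = ks.Snapshot(
        time=0.0,
        streamline_idx=np.arange(n_lines),
        s_kin=np.full(n_lines, s_kin),
        s_minus=np.full(n_lines, 0.5),
        birth_time=np.zeros(n_lines),
    )
    speed = fb.SpeedProfile(
        s=np.linspace(0, s_kin + 1, 50),
        v=np.full(50, v_const),
        r=0.4,
    )
    return snap, lines, speed


class TestSimulatePhotoconversion:
    def test_line_translates_rigidly_at_constant_speed(self):
        v0 = 1.0
        snap, lines, speed = small_population(v_const=v0)
        img = pc.ImagingConfig(n_frames=8, noise_sd=0.0, gamma=0.4)
        # effectively disable turnover with a tiny detachment rate
        movie = pc.simulate_photoconversion(
            snap, lines, speed, activation_x=4.0, imaging=img,
            detachment_rate=1e-9, rng=np.random.default_rng(0),
        )
        res = pc.analyze_movie(movie)
        assert res.speed.speed_um_per_min == pytest.approx(v0, rel=0.05)

    def test_marked_tubulin_conserved_without_turnover(self):
        snap, lines, speed = small_population(v_const=0.3)
        img = pc.ImagingConfig(n_frames=6, noise_sd=0.0, blur_px=0.0)
        movie = pc.simulate_photoconversion(
            snap, lines, speed, activation_x=3.0, imaging=img,
            detachment_rate=1e-9, rng=np.random.default_rng(0),
        )
        totals = movie.frames.sum(axis=(1, 2))
        np.testing.assert_allclose(totals, totals[0], rtol=0.02)

    def test_intensity_decays_with_turnover_only(self):
        snap, lines, speed = small_population(v_const=0.0)
        img = pc.ImagingConfig(n_frames=20, noise_sd=0.0)
        r = 1.5
        rng = np.random.default_rng(42)
        totals = np.zeros(20)
        for rep in range(30):  # average over detachment realizations
            movie = pc.simulate_photoconversion(
                snap, lines, speed, activation_x=3.0, imaging=img,
                detachment_rate=r, rng=rng,
            )
            totals += movie.frames.sum(axis=(1, 2))
        t = np.arange(20) * img.frame_interval / 60.0
        expected = totals[0] * np.exp(-r * t)
        np.testing.assert_allclose(totals, expected, rtol=0.25)

    def test_activation_outside_spindle_rejected(self):
        snap, lines, speed = small_population()
        with pytest.raises(ValueError):
            pc.simulate_photoconversion(
                snap, lines, speed, activation_x=50.0,
                imaging=pc.ImagingConfig(), detachment_rate=0.4,
            )

    def test_peak_width_grows_in_bulk_simulation(self, default_stack):
        """Dispersion of per-KMT speeds broadens the line over time."""
        stack = default_stack
        cfg = ks.SimulationConfig(dt=0.01, nucleation_rate=4.0, burn_in=10, duration=0.5, seed=4)
        pop = ks.run_simulation(
            cfg, stack["streamlines"], stack["kin_s"], stack["kin_sl"],
            stack["speed"], pin_floor=stack["pin_floor"],
        )
        img = pc.ImagingConfig(n_frames=13, noise_sd=0.0)
        movie = pc.simulate_photoconversion(
            pop.snapshots[-1], stack["streamlines"], stack["speed"],
            activation_x=-2.0, imaging=img, detachment_rate=0.4,
            rng=np.random.default_rng(1), pin_floor=stack["pin_floor"],
        )
        widths = []
        prev = None
        for f in range(movie.n_frames):
            prof = pc.extract_line_profile(movie, f)
            pk = pc.fit_peak(prof, previous_center=prev, window=9)
            if pk.valid:
                prev = pk.center_um
                widths.append(pk.width_um)
        # monotone trend, not magnitude: late widths exceed early widths
        assert np.mean(widths[-4:]) > np.mean(widths[:4])


class TestClosureWithGenerator:
    def test_full_chain_recovers_generator_parameters(self):
        """Movie generator → analysis chain closes on speed, slow fraction
        and both lifetimes within 5%."""
        cfg = sd.SyntheticMovieConfig(
            speed=1.2, activation_x0=3.5, noise_sd=0.5, bleach_rate=0.1, seed=3
        )
        movie, gt = sd.generate_movie(cfg)
        res = pc.analyze_movie(movie, bleach=sd.bleach_curve(cfg))
        assert res.speed.speed_um_per_min == pytest.approx(1.2, rel=0.05)
        assert res.speed.initial_position_um == pytest.approx(3.5, abs=0.15)
        assert res.turnover.slow_fraction == pytest.approx(0.26, rel=0.05)
        assert res.turnover.lifetime_slow_min == pytest.approx(2.8, rel=0.05)
        assert res.turnover.lifetime_fast_min == pytest.approx(0.26, rel=0.05)
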