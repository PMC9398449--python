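"""Orientation statistics: segment angles, ⟨θ⟩, S, averaging, geometry fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kfibers import nematic_field as nf
from kfibers import orientation_analysis as oa
from kfibers import synthetic_data as sd
from kfibers.spindle_io import KMT, MicrotubulePolyline, SpindleReconstruction


def rec_with_mts(mts):
    return SpindleReconstruction(
        mts=tuple(mts),
        poles=np.array([[-5.0, 0, 0], [5.0, 0, 0]]),
        kinetochores=(),
    )


class TestSegmentAngles:
    def test_straight_axial_mt_has_zero_angles(self):
        mt = MicrotubulePolyline(
            points=np.array([[0.0, 1.0, 0.0], [3.0, 1.0, 0.0]]), plus_end=0, minus_end=1
        )
        seg = oa.segment_angles(rec_with_mts([mt]))
        assert np.allclose(seg["angle"], 0.0, atol=1e-9)
        assert np.allclose(seg["axial_fraction"], 1.0)

    def test_quarter_circle_sweeps_angles_and_arc_length(self):
        R = 2.0
        t = np.linspace(0, np.pi / 2, 200)
        pts = np.stack([R * np.sin(t), R * (1 - np.cos(t)), np.zeros_like(t)], axis=1)
        mt = MicrotubulePolyline(points=pts, plus_end=0, minus_end=len(t) - 1)
        seg = oa.segment_angles(rec_with_mts([mt]), segment_len=0.05)
        assert seg["length"].sum() == pytest.approx(np.pi * R / 2, rel=0.01)
        # angles sweep the quarter turn
        assert seg["angle"].min() < np.radians(5)
        assert seg["angle"].abs().max() > np.radians(80)

    def test_segment_count_scales_with_length(self):
        mt = MicrotubulePolyline(
            points=np.array([[0.0, 0, 0], [4.0, 0, 0]]), plus_end=0, minus_end=1
        )
        seg = oa.segment_angles(rec_with_mts([mt]), segment_len=0.1)
        assert len(seg) == pytest.approx(4.0 / 0.1, abs=1)


class TestMeanOrientation:
    def test_headless_pair_averages_to_base_angle(self):
        th0 = 0.4
        assert oa.mean_orientation(np.array([th0, th0 + np.pi])) == pytest.approx(th0)

    def test_symmetric_pair_averages_to_zero(self):
        got = oa.mean_orientation(np.radians([10.0, -10.0]))
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_sample_recovers_mean(self):
        rng = np.random.default_rng(0)
        angles = np.radians(30) + rng.vonmises(0.0, 20.0, 10_000) / 2
        got = oa.mean_orientation(angles)
        assert np.degrees(got) == pytest.approx(30.0, abs=1.0)

    def test_balanced_bimodal_flagged_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            oa.mean_orientation(np.array([np.pi / 4, -np.pi / 4]))

    @given(st.floats(-1.5, 1.5), st.floats(-0.7, 0.7))
    @settings(max_examples=25, deadline=None)
    def test_rotation_equivariance(self, base, shift):
        rng = np.random.default_rng(3)
        angles = base + rng.normal(0, 0.2, 200)
        m0 = oa.mean_orientation(angles)
        m1 = oa.mean_orientation(angles + shift)
        d = np.mod(m1 - m0 - shift + np.pi / 2, np.pi) - np.pi / 2
        assert abs(d) < 1e-9


class TestOrderParameter:
    def test_aligned_is_one(self):
        assert oa.order_parameter(np.full(50, 0.3)) == pytest.approx(1.0)

    def test_isotropic_3d_is_zero(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(40_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        theta = np.arccos(v[:, 2])  # polar angle from the reference axis
        S = oa.order_parameter(theta, mean=0.0)
        assert abs(S) < 3.0 / np.sqrt(len(theta))

    def test_perpendicular_is_minus_half(self):
        S = oa.order_parameter(np.full(10, np.pi / 2), mean=0.0)
        assert S == pytest.approx(-0.5)

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(2)
        angles = rng.uniform(-np.pi / 2, np.pi / 2, 500)
        w = rng.uniform(0.5, 2.0, 500)
        mean = oa.mean_orientation(angles, w)
        brute = np.sum(w * 0.5 * (3 * np.cos(angles - mean) ** 2 - 1)) / np.sum(w)
        assert oa.order_parameter(angles, w, mean=mean) == pytest.approx(brute)

    def test_2d_estimator_isotropic_in_plane_is_zero(self):
        rng = np.random.default_rng(4)
        angles = rng.uniform(-np.pi / 2, np.pi / 2, 20_000)
        S = oa.order_parameter(angles, mean=0.0, estimator="2d")
        assert abs(S) < 3.0 / np.sqrt(len(angles))

    @given(st.floats(-0.7, 0.7))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_global_rotation(self, shift):
        rng = np.random.default_rng(5)
        angles = rng.normal(0.2, 0.3, 300)
        S0 = oa.order_parameter(angles)
        S1 = oa.order_parameter(angles + shift)
        assert S1 == pytest.approx(S0, abs=1e-9)


class TestRotationalAverage:
    def test_single_off_axis_mt_appears_in_all_rotated_copies(self):
        mt = MicrotubulePolyline(
            points=np.array([[0.0, 2.0, 0.0], [1.0, 2.0, 0.0]]),
            plus_end=0,
            minus_end=1,
        )
        binned = oa.rotational_average(rec_with_mts([mt]), bin_size=0.5, segment_len=0.5)
        # 20 rotations × 2 segments... each segment contributes one copy
        # per rotation; total count equals segments × 20
        n_seg = len(oa.segment_angles(rec_with_mts([mt]), segment_len=0.5))
        assert binned.count.sum() == n_seg * 20

    def test_axisymmetric_spindle_is_a_fixed_point(self):
        cfg = sd.SyntheticSpindleConfig(
            n_kmts=40, n_nonkmts=0, kappa=None, azimuthal=True, seed=4
        )
        rec, _ = sd.generate_spindle(cfg)
        rng = ((-6.5, 6.5), (-4.0, 4.0))
        b1 = oa.rotational_average(rec, bin_size=0.5, x_range=rng[0], y_range=rng[1])
        b2 = oa.rotational_average(
            rec, bin_size=0.5, rotation_step=np.pi / 5, x_range=rng[0], y_range=rng[1]
        )
        both = b1.occupied() & b2.occupied() & (b1.count > 40) & (b2.count > 40)
        d = np.abs(
            np.mod(b1.angle[both] - b2.angle[both] + np.pi / 2, np.pi) - np.pi / 2
        )
        assert np.nanmean(d) < 0.1

    def test_binned_angles_match_generator_field(self, synthetic_spindle):
        rec, gt = synthetic_spindle
        binned = oa.rotational_average(rec, cls=KMT, bin_size=0.4)
        X, Y = np.meshgrid(binned.x_centers, binned.y_centers)
        occ = binned.occupied() & (binned.count > 30)
        pts = np.stack([X[occ], Y[occ]], axis=1)
        inside = gt.field.geometry.inside(pts[:, 0], np.abs(pts[:, 1]))
        model = gt.field.angle_at(np.stack([pts[:, 0], np.abs(pts[:, 1])], axis=1))
        # generator lies in the z=0 plane: compare against |y| half-plane
        meas = binned.angle[occ]
        d = np.abs(np.mod(np.abs(meas[inside]) - np.abs(model[inside]) + np.pi / 2, np.pi) - np.pi / 2)
        assert np.mean(d) < 0.15


class TestRegistration:
    def make_field(self, scale=1.0, seed=0, noise=0.0):
        geom = nf.SpindleGeometry(
            a=5.0 * scale, b=3.0 * scale, defect_x=(-4.0 * scale, 4.0 * scale),
            defect_radius=0.5 * scale,
        )
        fld = nf.solve_director(geom, spacing=0.25 * scale, tol=1e-5)
        omap = sd.generate_orientation_map(fld, noise_sd=noise, seed=seed)
        angle = np.where(omap.weight > 0, omap.angle, np.nan)
        return oa.BinnedOrientationField(
            angle=angle,
            S=np.ones_like(angle),
            count=(omap.weight > 0).astype(int),
            weight=omap.weight,
            x_edges=np.concatenate([fld.x - fld.spacing / 2, [fld.x[-1] + fld.spacing / 2]]),
            y_edges=np.concatenate([fld.y - fld.spacing / 2, [fld.y[-1] + fld.spacing / 2]]),
            bin_size=fld.spacing,
        ), fld

    def test_single_item_identity(self):
        f, _ = self.make_field()
        out = oa.register_spindles([f])
        assert out is f

    def test_rescaled_copy_averages_to_original(self):
        f1, fld1 = self.make_field(scale=1.0)
        f2, _ = self.make_field(scale=2.0)
        avg = oa.register_spindles([f1, f2])
        both = avg.count > 0
        ref = np.isfinite(f1.angle)
        common = both & ref
        d = np.abs(
            np.mod(avg.angle[common] - f1.angle[common] + np.pi / 2, np.pi) - np.pi / 2
        )
        assert np.nanmean(d) < 0.05

    def test_averaging_noisy_maps_reduces_error(self):
        fields = []
        truth = None
        for seed in range(3):
            f, fld = self.make_field(noise=0.25, seed=seed)
            fields.append(f)
            truth = fld
        avg = oa.register_spindles(fields)
        X, Y = np.meshgrid(fields[0].x_centers, fields[0].y_centers)
        occ = avg.count > 0
        pts = np.stack([X[occ], Y[occ]], axis=1)
        model = truth.angle_at(pts)

        def rms(field):
            a = field.angle[occ]
            ok = np.isfinite(a)
            d = np.mod(a[ok] - model[ok] + np.pi / 2, np.pi) - np.pi / 2
            return np.sqrt(np.mean(d**2))

        assert rms(avg) < min(rms(f) for f in fields)


@pytest.fixture(scope="module")
def noiseless_case():
    geom = nf.SpindleGeometry(a=5.0, b=3.0, defect_x=(-4.0, 4.0), defect_radius=0.5)
    fld = nf.solve_director(geom, spacing=0.25, tol=1e-5)
    omap = sd.generate_orientation_map(fld, noise_sd=0.0, seed=0)
    angle = np.where(omap.weight > 0, omap.angle, np.nan)
    bof = oa.BinnedOrientationField(
        angle=angle,
        S=np.ones_like(angle),
        count=(omap.weight > 0).astype(int),
        weight=omap.weight,
        x_edges=np.concatenate([fld.x - fld.spacing / 2, [fld.x[-1] + fld.spacing / 2]]),
        y_edges=np.concatenate([fld.y - fld.spacing / 2, [fld.y[-1] + fld.spacing / 2]]),
        bin_size=fld.spacing,
    )
    return geom, bof


class TestFitGeometry:
    def test_recovers_known_geometry(self, noiseless_case):
        geom, bof = noiseless_case
        best, chi2 = oa.fit_geometry(bof, solver_spacing=0.4)
        assert best.defect_x[0] == pytest.approx(geom.defect_x[0], abs=0.4)
        assert best.defect_x[1] == pytest.approx(geom.defect_x[1], abs=0.4)
        assert chi2 < 0.02

    def test_displaced_defects_fit_worse(self, noiseless_case):
        geom, bof = noiseless_case
        best, chi2 = oa.fit_geometry(bof, solver_spacing=0.4)
        displaced = nf.SpindleGeometry(
            a=best.a,
            b=best.b,
            defect_x=(-0.8, 0.8),
            defect_radius=best.defect_radius,
            center=best.center,
        )
        assert oa.chi2_at(bof, displaced, solver_spacing=0.4) > 3 * chi2

    def test_too_few_bins_rejected(self):
        empty = oa.BinnedOrientationField(
            angle=np.full((3, 3), np.nan),
            S=np.full((3, 3), np.nan),
            count=np.zeros((3, 3), dtype=int),
            weight=np.zeros((3, 3)),
            x_edges=np.arange(4.0),
            y_edges=np.arange(4.0),
            bin_size=1.0,
        )
        with pytest.raises(ValueError):
            oa.fit_geometry(empty)
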