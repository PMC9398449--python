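"""IO contracts: round trips, schema validation, KMT classification."""

import numpy as np
import pytest

from kfibers import spindle_io as sio
from kfibers.spindle_io import (
    KMT,
    NON_KMT,
    MicrotubulePolyline,
    PhotoconversionMovie,
    OrientationMap,
    SchemaError,
    SpindleReconstruction,
)


class TestReconstructionIO:
    def test_round_trip_is_bit_exact(self, toy_reconstruction, tmp_path):
        path = tmp_path / "rec"
        sio.save_reconstruction(toy_reconstruction, path)
        back = sio.load_reconstruction(path)
        assert len(back.mts) == len(toy_reconstruction.mts)
        for a, b in zip(back.mts, toy_reconstruction.mts):
            np.testing.assert_array_equal(a.points, b.points)
            assert (a.cls, a.kinetochore_id, a.plus_end, a.minus_end) == (
                b.cls,
                b.kinetochore_id,
                b.plus_end,
                b.minus_end,
            )
        np.testing.assert_array_equal(back.poles, toy_reconstruction.poles)
        assert back.meta["source"] == "unit-test"

    def test_single_kmt_loads_with_class(self, tmp_path):
        rec = SpindleReconstruction(
            mts=(
                MicrotubulePolyline(
                    points=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
                    plus_end=0,
                    minus_end=1,
                    cls=KMT,
                    kinetochore_id=1,
                    mt_id=0,
                ),
            ),
            poles=np.array([[-1.0, 0, 0], [2.0, 0, 0]]),
            kinetochores=((1, np.array([0.0, 0.0, 0.0])),),
        )
        path = tmp_path / "one"
        sio.save_reconstruction(rec, path)
        back = sio.load_reconstruction(path)
        assert len(back.mts) == 1 and back.mts[0].cls == KMT

    @pytest.mark.parametrize(
        "mutation",
        ["kmt_without_kinetochore", "nonfinite", "one_point", "bad_ends"],
    )
    def test_schema_violations_raise(self, mutation):
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        kwargs = dict(points=pts, plus_end=0, minus_end=1, cls=NON_KMT)
        if mutation == "kmt_without_kinetochore":
            kwargs.update(cls=KMT, kinetochore_id=None)
        elif mutation == "nonfinite":
            kwargs.update(points=np.array([[0, 0, 0], [np.nan, 0, 0]]))
        elif mutation == "one_point":
            kwargs.update(points=pts[:1])
        elif mutation == "bad_ends":
            kwargs.update(points=np.vstack([pts, [2.0, 0, 0]]), minus_end=1)
        with pytest.raises(SchemaError):
            MicrotubulePolyline(**kwargs)

    def test_kmt_referencing_unknown_kinetochore_rejected(self):
        mt = MicrotubulePolyline(
            points=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            plus_end=0,
            minus_end=1,
            cls=KMT,
            kinetochore_id=99,
        )
        with pytest.raises(SchemaError, match="99"):
            SpindleReconstruction(
                mts=(mt,),
                poles=np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]],
                kinetochores=(),
            )


class TestClassifyKmts:
    def make_rec(self, mts, kts):
        return SpindleReconstruction(
            mts=tuple(mts),
            poles=np.array([[-5.0, 0, 0], [5.0, 0, 0]]),
            kinetochores=tuple(kts),
        )

    def test_terminus_at_kinetochore_becomes_plus_end(self):
        mt = MicrotubulePolyline(
            points=np.array([[0.0, 0, 0], [2.0, 0, 0]]), plus_end=0, minus_end=1
        )
        rec = self.make_rec([mt], [(3, np.array([2.0, 0.0, 0.0]))])
        out = sio.classify_kmts(rec, attach_radius=0.5)
        assert out.mts[0].cls == KMT
        assert out.mts[0].kinetochore_id == 3
        assert out.mts[0].plus_end == 1  # the terminus at the kinetochore

    def test_threshold_is_closed(self):
        mt = MicrotubulePolyline(
            points=np.array([[0.0, 0, 0], [2.0, 0, 0]]), plus_end=0, minus_end=1
        )
        rec = self.make_rec([mt], [(0, np.array([2.5, 0.0, 0.0]))])
        exactly = sio.classify_kmts(rec, attach_radius=0.5)
        assert exactly.mts[0].cls == KMT  # distance == radius counts
        beyond = sio.classify_kmts(rec, attach_radius=0.499)
        assert beyond.mts[0].cls == NON_KMT

    def test_matches_brute_force_over_random_mts(self):
        rng = np.random.default_rng(5)
        mts = [
            MicrotubulePolyline(
                points=rng.uniform(-5, 5, (3, 3)), plus_end=0, minus_end=2, mt_id=i
            )
            for i in range(100)
        ]
        kts = [(k, rng.uniform(-5, 5, 3)) for k in range(12)]
        rec = self.make_rec(mts, kts)
        radius = 1.2
        out = sio.classify_kmts(rec, attach_radius=radius)
        for mt_in, mt_out in zip(rec.mts, out.mts):
            termini = [mt_in.points[0], mt_in.points[-1]]
            dmin = min(
                np.linalg.norm(t - p) for t in termini for _, p in kts
            )
            assert (mt_out.cls == KMT) == (dmin <= radius), mt_in.mt_id

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        mts = [
            MicrotubulePolyline(
                points=rng.uniform(-5, 5, (2, 3)), plus_end=0, minus_end=1, mt_id=i
            )
            for i in range(30)
        ]
        rec = self.make_rec(mts, [(0, np.zeros(3))])
        once = sio.classify_kmts(rec, attach_radius=2.0)
        twice = sio.classify_kmts(once, attach_radius=2.0)
        for a, b in zip(once.mts, twice.mts):
            assert (a.cls, a.kinetochore_id, a.plus_end) == (b.cls, b.kinetochore_id, b.plus_end)

    def test_no_kinetochores_means_all_non_kmt(self):
        mt = MicrotubulePolyline(
            points=np.array([[0.0, 0, 0], [1.0, 0, 0]]), plus_end=0, minus_end=1
        )
        out = sio.classify_kmts(self.make_rec([mt], []), attach_radius=1.0)
        assert all(m.cls == NON_KMT for m in out.mts)


class TestMinusEndPoleDistances:
    def test_distances_and_closed_threshold(self):
        poles = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        mts = [
            # minus end exactly at the pole
            MicrotubulePolyline(
                points=np.array([[2.0, 0, 0], [0.0, 0, 0]]),
                plus_end=0, minus_end=1, cls=KMT, kinetochore_id=0, mt_id=0,
            ),
            # minus end exactly at the 1.7 µm threshold
            MicrotubulePolyline(
                points=np.array([[3.0, 0, 0], [1.7, 0, 0]]),
                plus_end=0, minus_end=1, cls=KMT, kinetochore_id=0, mt_id=1,
            ),
        ]
        rec = SpindleReconstruction(
            mts=tuple(mts), poles=poles, kinetochores=((0, np.array([3.0, 0.0, 0.0])),)
        )
        df = sio.minus_end_pole_distances(rec)
        assert df.loc[0, "distance_um"] == 0.0
        assert df.loc[1, "distance_um"] == pytest.approx(1.7)
        assert bool(df.loc[1, "within"])  # closed interval
        assert df.attrs["fraction_within"] == 1.0

    def test_fraction_matches_generator_ground_truth(self):
        rng = np.random.default_rng(2)
        poles = np.array([[0.0, 0, 0], [12.0, 0, 0]])
        n, frac = 200, 0.30
        near = rng.uniform(0, 1.7, int(n * frac))
        far = rng.uniform(1.71, 5.0, n - int(n * frac))
        dists = np.concatenate([near, far])
        mts = [
            MicrotubulePolyline(
                points=np.array([[5.0, 0, 0], [d, 0, 0]]),
                plus_end=0, minus_end=1, cls=KMT, kinetochore_id=0, mt_id=i,
            )
            for i, d in enumerate(dists)
        ]
        rec = SpindleReconstruction(
            mts=tuple(mts), poles=poles, kinetochores=((0, np.array([5.0, 0.0, 0.0])),)
        )
        df = sio.minus_end_pole_distances(rec)
        assert df.attrs["fraction_within"] == pytest.approx(frac, abs=1e-12)

    def test_requires_kmts(self, toy_reconstruction):
        rec = SpindleReconstruction(
            mts=(toy_reconstruction.mts[1],),
            poles=toy_reconstruction.poles,
            kinetochores=(),
        )
        with pytest.raises(ValueError):
            sio.minus_end_pole_distances(rec)


class TestMovieAndMapIO:
    def test_movie_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        movie = PhotoconversionMovie(
            frames=rng.random((4, 8, 10)),
            pixel_size=0.1,
            frame_interval=5.0,
            pole_tracks=np.tile(np.array([[1.0, 4.0], [8.0, 4.0]]), (4, 1, 1)),
            activation_frame=1,
            activation_line=np.array([[3.0, 0.0], [3.0, 7.0]]),
        )
        sio.save_movie(movie, tmp_path / "mov")
        back = sio.load_movie(tmp_path / "mov")
        np.testing.assert_allclose(back.frames, movie.frames, atol=1e-6)
        np.testing.assert_array_equal(back.pole_tracks, movie.pole_tracks)
        assert back.activation_frame == 1

    def test_movie_invariants(self):
        with pytest.raises(SchemaError):
            PhotoconversionMovie(
                frames=np.zeros((3, 4, 4)),
                pixel_size=0.1,
                frame_interval=5.0,
                pole_tracks=np.full((3, 2, 2), np.nan),
            )

    def test_orientation_map_round_trip_and_wrapping(self, tmp_path):
        omap = OrientationMap(
            angle=np.array([[0.2, np.pi + 0.2], [-0.3, 1.0]]),
            weight=np.ones((2, 2)),
            bin_size=0.1,
        )
        # angles canonicalized modulo π
        assert omap.angle[0, 1] == pytest.approx(0.2)
        sio.save_orientation_map(omap, tmp_path / "om")
        back = sio.load_orientation_map(tmp_path / "om")
        np.testing.assert_allclose(back.angle, omap.angle, atol=1e-12)
        assert back.bin_size == 0.1

    def test_validate_detects_kind(self, toy_reconstruction, tmp_path):
        sio.save_reconstruction(toy_reconstruction, tmp_path / "rec")
        assert sio.validate(tmp_path / "rec") == "reconstruction"
        with pytest.raises(FileNotFoundError):
            sio.validate(tmp_path / "nothing")
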