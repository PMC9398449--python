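"""Shared fixtures: small solved fields and synthetic stacks, cached per session."""

from __future__ import annotations

import numpy as np
import pytest

from kfibers import flux_balance, nematic_field, synthetic_data
from kfibers.spindle_io import (
    KMT,
    NON_KMT,
    MicrotubulePolyline,
    SpindleReconstruction,
)


@pytest.fixture(scope="session")
def radial_disk_field():
    """Disk with coincident central defects and radial anchoring: the
    exact solution is the pure aster θ = atan2(y, x)."""
    geom = nematic_field.SpindleGeometry(
        a=4.0, b=4.0, defect_x=(0.0, 0.0), defect_radius=0.5
    )
    return nematic_field.solve_director(geom, spacing=0.05, tol=1e-6, boundary="radial")


@pytest.fixture(scope="session")
def spindle_geometry():
    return synthetic_data.default_geometry()


@pytest.fixture(scope="session")
def spindle_field(spindle_geometry):
    return nematic_field.solve_director(spindle_geometry, spacing=0.15, tol=1e-5)


@pytest.fixture(scope="session")
def streamlines(spindle_field):
    return nematic_field.seed_streamlines(spindle_field, spacing=0.5)


@pytest.fixture(scope="session")
def default_stack():
    """Geometry → field → streamlines → nucleate-model speed profile."""
    from kfibers.cli import build_default_stack

    return build_default_stack(seed=0)


@pytest.fixture(scope="session")
def synthetic_spindle():
    cfg = synthetic_data.SyntheticSpindleConfig(n_kmts=80, n_nonkmts=120, seed=11)
    return synthetic_data.generate_spindle(cfg)


def simple_reconstruction() -> SpindleReconstruction:
    """Two-MT toy spindle used by the IO contract tests."""
    kmt = MicrotubulePolyline(
        points=np.array([[4.0, 1.0, 0.0], [1.0, 0.5, 0.0], [-1.0, 0.0, 0.0]]),
        plus_end=0,
        minus_end=2,
        cls=KMT,
        kinetochore_id=7,
        mt_id=0,
    )
    free = MicrotubulePolyline(
        points=np.array([[0.0, -1.0, 0.5], [2.0, -1.5, 0.25]]),
        plus_end=1,
        minus_end=0,
        cls=NON_KMT,
        mt_id=1,
    )
    return SpindleReconstruction(
        mts=(kmt, free),
        poles=np.array([[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]]),
        kinetochores=((7, np.array([4.0, 1.0, 0.0])),),
        meta={"source": "unit-test"},
    )


@pytest.fixture
def toy_reconstruction():
    return simple_reconstruction()


@pytest.fixture(scope="session")
def density_profile_fn():
    """The default Gaussian-plus-constant minus-end density."""
    cfg = synthetic_data.SyntheticSpindleConfig()
    return cfg.minus_end_density


@pytest.fixture(scope="session")
def nucleate_speed(density_profile_fn):
    v = flux_balance.solve_speed(
        density_profile_fn, flux_balance.nucleate_model(), r=0.4, s_max=8.0
    )
    return flux_balance.treadmill_profile(v)
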