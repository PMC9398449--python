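"""Synthetic spindles, photoconversion movies and orientation maps.

Every generator carries its ground truth so each analysis stage can be
tested closed-loop: a spindle generator lays microtubules along the
streamlines of a prescribed director field with von-Mises angular noise
(applied in the doubled-angle representation, respecting the headless
symmetry) and draws KMT minus-end arc-length positions from a known
density n(s) — a Gaussian peaked near the pole plus a constant bulk
term; a movie generator renders an advecting, decaying, bleaching
photoconverted line with a modified-Cauchy cross-section from a known
speed field and known slow/fast turnover rates; an orientation-map
generator samples the model field with wrapped Gaussian noise.

Default parameter values follow the measured metaphase conditions: KMT
detachment rate 0.4 min⁻¹ (slow lifetime 2.8 min), non-KMT lifetime
0.26 min, slow-turnover fraction 0.26, mean non-KMT length 2.0 µm,
pole-peak position ~1 µm, 5 s frame interval, 0.1 µm pixels and a
1.0 µm axial activation width.  A fixed seed gives byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from kfibers import flux_balance, nematic_field
from kfibers.photoconversion import modified_cauchy
from kfibers.spindle_io import (
    KMT,
    NON_KMT,
    MicrotubulePolyline,
    OrientationMap,
    PhotoconversionMovie,
    SpindleReconstruction,
)


def default_geometry() -> nematic_field.SpindleGeometry:
    """HeLa-like metaphase spindle: 11 µm pole–pole, 3.5 µm half-width."""
    return nematic_field.SpindleGeometry(
        a=6.0, b=3.5, defect_x=(-5.0, 5.0), defect_radius=0.5
    )


@dataclass(frozen=True)
class SyntheticSpindleConfig:
    """Ground-truth parameters of a generated spindle reconstruction.

    The KMT minus-end density along streamlines is
    n(s) ∝ peak_amplitude·exp(−(s − peak_center)²/(2 σ_peak²)) + bulk_constant
    on [pole floor, s_kin].  ``kappa`` is the von-Mises concentration of
    the angular noise in the doubled-angle representation (∞ or None =
    perfectly aligned, 0 = isotropic in-plane); the implied 2D order
    parameter is I₁(κ)/I₀(κ).
    """

    geometry: nematic_field.SpindleGeometry = field(default_factory=default_geometry)
    n_kmts: int = 200
    n_nonkmts: int = 400
    peak_amplitude: float = 1.0
    peak_center: float = 1.0
    sigma_peak: float = 0.6
    bulk_constant: float = 0.5
    nonkmt_mean_length: float = 2.0
    kappa: Optional[float] = 50.0
    segment_len: float = 0.1
    azimuthal: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_kmts < 0 or self.n_nonkmts < 0:
            raise ValueError("counts must be >= 0")
        if self.sigma_peak <= 0:
            raise ValueError("sigma_peak must be positive")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    def minus_end_density(self, s: np.ndarray) -> np.ndarray:
        return flux_balance.gaussian_plus_constant(
            s, self.peak_amplitude, self.peak_center, self.sigma_peak, self.bulk_constant
        )


@dataclass
class SpindleGroundTruth:
    """What the generator actually did (per-MT, before measurement noise)."""

    field: nematic_field.DirectorField
    kmt_minus_s: np.ndarray
    kmt_kin_s: np.ndarray
    kmt_lengths: np.ndarray
    nonkmt_lengths: np.ndarray
    kappa: Optional[float]
    expected_order_2d: float
    config: SyntheticSpindleConfig


def _expected_order_2d(kappa: Optional[float]) -> float:
    from scipy.special import i0, i1

    if kappa is None or np.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


def _sample_density(
    rng: np.random.Generator, density: Callable[[np.ndarray], np.ndarray],
    lo: float, hi: float, n: int,
) -> np.ndarray:
    """Inverse-CDF sampling of a 1D density on [lo, hi]."""
    grid = np.linspace(lo, hi, 512)
    w = np.clip(np.asarray(density(grid), dtype=float), 0.0, None)
    if w.sum() <= 0:
        raise ValueError("density vanishes on the sampling interval")
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def _noisy_walk(
    field2d: nematic_field.DirectorField,
    start: np.ndarray,
    target_pole_center: np.ndarray,
    total_length: float,
    kappa: Optional[float],
    rng: np.random.Generator,
    step: float,
    toward_pole: bool = True,
) -> np.ndarray:
    """Grow a polyline along the director field with angular noise.

    Each segment's angle is the local director angle plus δ/2 with
    δ ~ von Mises(0, κ) drawn in the doubled-angle representation; the
    headless sign is fixed toward (or away from) the pole.
    """
    pts = [np.asarray(start, dtype=float)]
    p = pts[0].copy()
    n_steps = max(1, int(round(total_length / step)))
    geom = field2d.geometry
    for k in range(n_steps):
        th = float(field2d.angle_at(p[None, :])[0])
        if kappa is None or np.isinf(kappa):
            delta = 0.0
        else:
            delta = float(rng.vonmises(0.0, kappa)) if kappa > 0 else float(
                rng.uniform(-np.pi, np.pi)
            )
        ang = th + delta / 2.0
        d = np.array([np.cos(ang), np.sin(ang)])
        to_pole = target_pole_center - p
        sgn = np.sign(np.dot(d, to_pole))
        if sgn == 0:
            sgn = 1.0
        if not toward_pole:
            sgn = -sgn
        seg = step if k < n_steps - 1 else total_length - step * (n_steps - 1)
        p_new = p + sgn * d * seg
        if not geom.inside(np.array(p_new[0]), np.array(p_new[1])):
            break  # stop at the boundary rather than leave the spindle
        pts.append(p_new)
        p = p_new
    if len(pts) == 1:
        pts.append(p + np.array([step / 2, 0.0]))
    return np.asarray(pts)


def generate_spindle(
    cfg: SyntheticSpindleConfig,
    solver_spacing: float = 0.15,
    solver_tol: float = 1e-5,
) -> tuple[SpindleReconstruction, SpindleGroundTruth]:
    """Generate a spindle reconstruction with known ground truth.

    Kinetochores sit near the metaphase plate (spindle equator); each
    anchors one KMT whose plus end is at the kinetochore and whose
    minus-end arc-length position is drawn from the configured n(s) on
    its streamline.  KMT paths follow the director field with von-Mises
    angular noise; non-KMTs start at random interior points with
    exponential lengths.  With ``azimuthal=True`` each microtubule's
    plane is rotated by a random azimuth about the spindle axis,
    producing an axisymmetric 3D spindle; otherwise everything lies in
    the z = 0 central slice.
    """
    rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry
    field2d = nematic_field.solve_director(geom, spacing=solver_spacing, tol=solver_tol)
    cx, cy = geom.center
    pole_centers = geom.defect_centers

    mts: list[MicrotubulePolyline] = []
    kinetochores: list[tuple[int, np.ndarray]] = []
    kmt_minus_s, kmt_kin_s, kmt_lengths = [], [], []
    step = cfg.segment_len

    def embed(pts2d: np.ndarray, phi: float) -> np.ndarray:
        y = pts2d[:, 1] - cy
        out = np.stack(
            [pts2d[:, 0], cy + y * np.cos(phi), y * np.sin(phi)], axis=1
        )
        return out

    mt_id = 0
    for k in range(cfg.n_kmts):
        # kinetochore near the equatorial plate
        for _ in range(100):
            kx = cx + rng.normal(0.0, 0.4)
            ky = cy + rng.uniform(-0.9, 0.9) * geom.b * 0.85
            if geom.inside(np.array(kx), np.array(ky)):
                break
        kt2d = np.array([kx, ky])
        pole = int(np.argmin(np.linalg.norm(pole_centers - kt2d[None, :], axis=1)))
        sl = nematic_field.trace_streamline(field2d, kt2d, pole)
        s_kin = sl.s_max
        lo = geom.defect_radius
        if s_kin <= lo + 2 * step:
            continue
        s_minus = float(
            _sample_density(rng, cfg.minus_end_density, lo, s_kin, 1)[0]
        )
        length = s_kin - s_minus
        pts2d = _noisy_walk(
            field2d, kt2d, pole_centers[pole], length, cfg.kappa, rng, step
        )
        phi = rng.uniform(0, 2 * np.pi) if cfg.azimuthal else 0.0
        pts3d = embed(pts2d, phi)
        kt3d = pts3d[0]
        kinetochores.append((k, kt3d))
        mts.append(
            MicrotubulePolyline(
                points=pts3d,
                plus_end=0,
                minus_end=len(pts3d) - 1,
                cls=KMT,
                kinetochore_id=k,
                mt_id=mt_id,
            )
        )
        mt_id += 1
        kmt_minus_s.append(s_minus)
        kmt_kin_s.append(s_kin)
        kmt_lengths.append(length)

    nonkmt_lengths = []
    for _ in range(cfg.n_nonkmts):
        for _ in range(100):
            px = cx + rng.uniform(-geom.a, geom.a)
            py = cy + rng.uniform(-geom.b, geom.b)
            if geom.inside(np.array(px * 0.95), np.array(py * 0.95)) and geom.inside(
                np.array(px), np.array(py)
            ):
                break
        start = np.array([px, py])
        length = float(rng.exponential(cfg.nonkmt_mean_length))
        length = max(length, 2 * step)
        pole = int(np.argmin(np.linalg.norm(pole_centers - start[None, :], axis=1)))
        pts2d = _noisy_walk(
            field2d,
            start,
            pole_centers[pole],
            length,
            cfg.kappa,
            rng,
            step,
            toward_pole=bool(rng.integers(0, 2)),
        )
        phi = rng.uniform(0, 2 * np.pi) if cfg.azimuthal else 0.0
        pts3d = embed(pts2d, phi)
        actual_len = float(np.sum(np.linalg.norm(np.diff(pts3d, axis=0), axis=1)))
        if actual_len <= 0:
            continue
        mts.append(
            MicrotubulePolyline(
                points=pts3d,
                plus_end=0,
                minus_end=len(pts3d) - 1,
                cls=NON_KMT,
                mt_id=mt_id,
            )
        )
        mt_id += 1
        nonkmt_lengths.append(actual_len)

    poles3d = np.array(
        [[pole_centers[0][0], pole_centers[0][1], 0.0], [pole_centers[1][0], pole_centers[1][1], 0.0]]
    )
    rec = SpindleReconstruction(
        mts=tuple(mts),
        poles=poles3d,
        kinetochores=tuple(kinetochores),
        meta={"generator": "kfibers.synthetic_data", "seed": cfg.seed},
    )
    gt = SpindleGroundTruth(
        field=field2d,
        kmt_minus_s=np.asarray(kmt_minus_s),
        kmt_kin_s=np.asarray(kmt_kin_s),
        kmt_lengths=np.asarray(kmt_lengths),
        nonkmt_lengths=np.asarray(nonkmt_lengths),
        kappa=cfg.kappa,
        expected_order_2d=_expected_order_2d(cfg.kappa),
        config=cfg,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# photoconversion movies


@dataclass(frozen=True)
class SyntheticMovieConfig:
    """Ground truth for a generated photoconversion movie.

    Defaults reproduce experiment-like imaging: 5 s frames over 2.5 min,
    0.1 µm pixels, slow fraction 0.26 with lifetimes 2.8 min (KMT) and
    0.26 min (non-KMT), and a modified-Cauchy activation profile.
    ``speed`` maps distance-from-pole (µm) to µm/min (poleward).
    """

    speed: Callable[[np.ndarray], np.ndarray] | float = 1.0
    k_slow: float = 1.0 / 2.8
    k_fast: float = 1.0 / 0.26
    slow_fraction: float = 0.26
    bleach_rate: float = 0.0  # min⁻¹
    amplitude: float = 100.0
    gamma: float = 1.0  # µm
    cauchy_power: float = 1.0
    sigma_z: float = 1.0  # µm (recorded; 2D render uses it only as metadata)
    activation_x0: float = 3.0  # µm from pole 0
    spindle_length: float = 11.0  # µm pole-to-pole
    spindle_halfwidth: float = 3.0  # µm
    pixel_size: float = 0.1
    frame_interval: float = 5.0  # s
    duration: float = 2.5  # min
    noise_sd: float = 0.5
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.k_slow <= 0 or self.k_fast <= 0:
            raise ValueError("turnover rates must be positive")
        if not 0.0 <= self.slow_fraction <= 1.0:
            raise ValueError("slow fraction in [0, 1]")
        if self.sigma_z <= 0:
            raise ValueError("sigma_z must be positive")

    def speed_at(self, s: np.ndarray) -> np.ndarray:
        if callable(self.speed):
            return np.asarray(self.speed(np.asarray(s, dtype=float)), dtype=float)
        return np.full_like(np.asarray(s, dtype=float), float(self.speed))


@dataclass
class MovieGroundTruth:
    times_min: np.ndarray
    centers_um: np.ndarray  # true peak distance from pole 0
    amplitudes: np.ndarray  # true decay amplitude (before bleaching)
    config: SyntheticMovieConfig


def generate_movie(cfg: SyntheticMovieConfig) -> tuple[PhotoconversionMovie, MovieGroundTruth]:
    """Render an advected, decaying, bleaching photoconverted line.

    The line center c(t) obeys dc/dt = −v(c) from ``activation_x0``;
    the cross-section is a modified Cauchy of half-width γ; the height
    decays as the slow/fast mixture; bleaching multiplies every frame by
    e^{−βt}; Gaussian (and optional shot) noise is added per pixel.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration * 60.0 / cfg.frame_interval)) + 1
    t_min = np.arange(n_frames) * cfg.frame_interval / 60.0

    # advect the true center with small sub-steps
    centers = np.empty(n_frames)
    c = float(cfg.activation_x0)
    sub = 20
    dt = (cfg.frame_interval / 60.0) / sub
    for i in range(n_frames):
        centers[i] = c
        for _ in range(sub):
            c = max(c - float(cfg.speed_at(np.array(c))) * dt, 0.0)

    amps = cfg.amplitude * (
        cfg.slow_fraction * np.exp(-cfg.k_slow * t_min)
        + (1.0 - cfg.slow_fraction) * np.exp(-cfg.k_fast * t_min)
    )
    bleach = np.exp(-cfg.bleach_rate * t_min)

    margin = 1.0  # µm beyond the poles
    W = int(round((cfg.spindle_length + 2 * margin) / cfg.pixel_size))
    H = int(round(2 * (cfg.spindle_halfwidth + margin) / cfg.pixel_size))
    x_um = (np.arange(W) + 0.5) * cfg.pixel_size - margin  # distance from pole 0
    y_um = (np.arange(H) + 0.5) * cfg.pixel_size - (cfg.spindle_halfwidth + margin)
    band = (np.abs(y_um) <= cfg.spindle_halfwidth).astype(float)

    frames = np.empty((n_frames, H, W))
    for i in range(n_frames):
        prof = modified_cauchy(x_um - centers[i], cfg.gamma, cfg.cauchy_power)
        img = amps[i] * bleach[i] * band[:, None] * prof[None, :]
        if cfg.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        frames[i] = img

    pole0 = np.array([margin / cfg.pixel_size, H / 2.0])
    pole1 = np.array([(margin + cfg.spindle_length) / cfg.pixel_size, H / 2.0])
    tracks = np.broadcast_to(
        np.stack([pole0, pole1])[None, :, :], (n_frames, 2, 2)
    ).copy()
    movie = PhotoconversionMovie(
        frames=frames,
        pixel_size=cfg.pixel_size,
        frame_interval=cfg.frame_interval,
        pole_tracks=tracks,
        activation_frame=0,
        activation_line=np.array(
            [
                [(margin + cfg.activation_x0) / cfg.pixel_size, 0.0],
                [(margin + cfg.activation_x0) / cfg.pixel_size, H - 1.0],
            ]
        ),
        meta={"generator": "kfibers.synthetic_data", "seed": cfg.seed},
    )
    gt = MovieGroundTruth(times_min=t_min, centers_um=centers, amplitudes=amps, config=cfg)
    return movie, gt


def bleach_curve(cfg: SyntheticMovieConfig) -> np.ndarray:
    """The movie's bleaching calibration curve (normalized to 1 at t=0)."""
    n_frames = int(round(cfg.duration * 60.0 / cfg.frame_interval)) + 1
    t_min = np.arange(n_frames) * cfg.frame_interval / 60.0
    return np.exp(-cfg.bleach_rate * t_min)


# ---------------------------------------------------------------------------
# orientation maps


def generate_orientation_map(
    field2d: nematic_field.DirectorField,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> OrientationMap:
    """Sample the solved director field into a PolScope-like map.

    Per-cell angle = field angle + wrapped Gaussian noise (applied in
    the doubled-angle representation); weight = 1 inside the spindle
    (a flat microtubule-density proxy), 0 outside.
    """
    rng = np.random.default_rng(seed)
    theta = field2d.theta.copy()
    inside = np.isfinite(theta)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, theta.shape)
        theta = theta + noise
    theta = np.mod(theta + np.pi / 2, np.pi) - np.pi / 2
    theta[~inside] = 0.0
    weight = inside.astype(float)
    return OrientationMap(
        angle=theta,
        weight=weight,
        bin_size=field2d.spacing,
        origin=(float(field2d.x[0]), float(field2d.y[0])),
    )
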