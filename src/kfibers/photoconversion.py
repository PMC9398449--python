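"""Photoconversion experiments: movie analysis and forward simulation.

Analysis chain (mirrors how the experiments are processed): project the
marked-tubulin intensity onto the spindle axis by averaging a band of
pixels on either side of the pole–pole line; fit the activated peak in
each frame to a Gaussian over a small central window, tracking the
candidate nearest to the previous frame's peak; correct peak heights
for background (opposite-side Gaussian) and photobleaching (calibration
curve); fit the corrected heights to a dual-exponential decay

    I(t) = A_slow e^{−k_slow t} + A_fast e^{−k_fast t}

whose slow component reports KMT turnover and fast component non-KMT
turnover, with slow fraction A_slow/(A_slow + A_fast); and fit the peak
center vs time to a line for the tubulin speed (poleward positive).

The forward simulation marks tubulin on simulated KMTs with a modified
Cauchy line profile, advects marks along streamlines at the tubulin
speed v_tub(s) of the KMT's minus end, removes marks on detachment or
on reaching the (depolymerizing) minus end, and renders frames so the
same analysis chain can be applied to model output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage, optimize, signal

from kfibers.flux_balance import SpeedProfile
from kfibers.kmt_simulator import SimulatedKMTPopulation, Snapshot
from kfibers.nematic_field import Streamline
from kfibers.spindle_io import PhotoconversionMovie

log = logging.getLogger(__name__)


def modified_cauchy(x: np.ndarray, gamma: float, power: float = 1.0) -> np.ndarray:
    """Activation line profile 1 / (1 + (x/γ)²)^p (normalized to 1 at x=0).

    The photoconverted line's cross-section is heavier-tailed than a
    Gaussian; a Lorentzian-family profile with tunable tail exponent
    ``power`` fits it well (p = 1 is the plain Cauchy).
    """
    return (1.0 + (np.asarray(x, dtype=float) / gamma) ** 2) ** (-power)


# ---------------------------------------------------------------------------
# line profiles and peak tracking


@dataclass(frozen=True)
class LineProfile:
    """Band-averaged intensity vs signed distance from the pole (µm)."""

    pos_um: np.ndarray
    intensity: np.ndarray
    frame: int


@dataclass(frozen=True)
class PeakFit:
    center_um: float  # distance from the pole along the axis
    height: float
    width_um: float
    valid: bool = True


def extract_line_profile(
    movie: PhotoconversionMovie,
    frame: int,
    band_halfwidth: int = 15,
    sub_band_um: Optional[float] = None,
    pole: int = 0,
) -> LineProfile:
    """Project a frame onto the spindle axis by band averaging.

    The spindle axis is the line through the two pole markers of the
    frame; intensity is averaged over ``band_halfwidth`` pixels on
    either side of the axis (``sub_band_um`` instead restricts the band
    to ±that many µm, the "thin central section" control).  Positions
    are signed distances (µm) from ``pole`` along the axis toward the
    other pole.  Raises if the axis lies outside the frame.
    """
    img = movie.frames[frame]
    p0, p1 = movie.pole_tracks[frame]
    axis = p1 - p0
    L = np.linalg.norm(axis)
    if L <= 0:
        raise ValueError("coincident pole markers")
    ex = axis / L
    ey = np.array([-ex[1], ex[0]])
    if pole == 1:
        p0, ex = p1, -ex
    H, W = img.shape
    if not (0 <= p0[0] < W and 0 <= p0[1] < H):
        raise ValueError("pole marker outside the frame")

    if sub_band_um is not None:
        half = max(1, int(round(sub_band_um / movie.pixel_size)))
    else:
        half = band_halfwidth
    # sample positions from one pole beyond the other, 1 px steps
    margin = 0.15 * L
    ts = np.arange(-margin, L + margin, 1.0)
    offs = np.arange(-half, half + 1, 1.0)
    # coordinate grids: (n_off, n_t) in (x, y) pixels
    px = p0[0] + ts[None, :] * ex[0] + offs[:, None] * ey[0]
    py = p0[1] + ts[None, :] * ex[1] + offs[:, None] * ey[1]
    vals = ndimage.map_coordinates(img, [py, px], order=1, mode="nearest")
    prof = vals.mean(axis=0)
    return LineProfile(pos_um=ts * movie.pixel_size, intensity=prof, frame=frame)


def fit_peak(
    profile: LineProfile,
    previous_center: Optional[float] = None,
    window: int = 5,
    noise_floor_sigmas: float = 3.0,
) -> PeakFit:
    """Gaussian fit of the activated peak using the central ``window`` pixels.

    Candidate local maxima must exceed the noise floor (median + k·MAD);
    among candidates the one nearest ``previous_center`` is selected
    (the first frame uses the global maximum).  The Gaussian is fit to
    ``window`` samples centered on the candidate.  Returns an invalid
    flagged fit if no candidate clears the floor.
    """
    y = profile.intensity
    x = profile.pos_um
    med = np.median(y)
    mad = np.median(np.abs(y - med)) * 1.4826
    floor = med + noise_floor_sigmas * max(mad, 1e-12)
    peaks, _ = signal.find_peaks(y, height=floor)
    if len(peaks) == 0:
        return PeakFit(np.nan, np.nan, np.nan, valid=False)
    if previous_center is None:
        idx = peaks[int(np.argmax(y[peaks]))]
    else:
        idx = peaks[int(np.argmin(np.abs(x[peaks] - previous_center)))]
    hw = window // 2
    lo, hi = max(0, idx - hw), min(len(y), idx + hw + 1)
    xs, ys = x[lo:hi], y[lo:hi]
    dx = np.mean(np.diff(x))

    def gauss(xx, A, mu, sig):
        return A * np.exp(-((xx - mu) ** 2) / (2 * sig**2))

    try:
        popt, _ = optimize.curve_fit(
            gauss,
            xs,
            ys,
            p0=[y[idx], x[idx], 2 * dx],
            bounds=([0, xs[0] - dx, dx / 4], [np.inf, xs[-1] + dx, 20 * (xs[-1] - xs[0] + dx)]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return PeakFit(np.nan, np.nan, np.nan, valid=False)
    return PeakFit(center_um=float(popt[1]), height=float(popt[0]), width_um=float(popt[2]))


def fit_opposite_peak(profile: LineProfile, main_center: float, spindle_length: float,
                      window: int = 5) -> PeakFit:
    """Gaussian fit at the mirror position on the other half-spindle.

    Used as the background estimate: reflect the main peak's position
    across the spindle midpoint and fit a Gaussian in that window.
    """
    mirror = spindle_length - main_center
    x, y = profile.pos_um, profile.intensity
    idx = int(np.argmin(np.abs(x - mirror)))
    hw = window // 2
    lo, hi = max(0, idx - hw), min(len(y), idx + hw + 1)
    xs, ys = x[lo:hi], y[lo:hi]
    if len(xs) < 3 or np.all(ys <= 0):
        return PeakFit(mirror, 0.0, np.nan, valid=False)
    dx = np.mean(np.diff(x))

    def gauss(xx, A, mu, sig):
        return A * np.exp(-((xx - mu) ** 2) / (2 * sig**2))

    try:
        popt, _ = optimize.curve_fit(
            gauss, xs, ys, p0=[max(ys.max(), 1e-9), mirror, 2 * dx],
            bounds=([0, xs[0] - dx, dx / 4], [np.inf, xs[-1] + dx, 20 * (xs[-1] - xs[0] + dx)]),
            maxfev=2000,
        )
        return PeakFit(float(popt[1]), float(popt[0]), float(popt[2]))
    except (RuntimeError, ValueError):
        return PeakFit(mirror, float(np.clip(ys.mean(), 0, None)), np.nan, valid=False)


def correct_height(
    raw_heights: np.ndarray,
    opposite_heights: np.ndarray | float = 0.0,
    bleach: np.ndarray | float = 1.0,
    dark_level: float = 0.0,
) -> np.ndarray:
    """Background- and bleach-corrected peak heights.

    corrected(t) = (main(t) − opposite(t)) / bleach(t), with the bleach
    reference itself dark-corrected via ``dark_level`` before use.  The
    bleach curve must be normalized to 1 at t = 0 and strictly positive.
    """
    raw = np.asarray(raw_heights, dtype=float)
    opp = np.broadcast_to(np.asarray(opposite_heights, dtype=float), raw.shape)
    b = np.broadcast_to(np.asarray(bleach, dtype=float), raw.shape) - dark_level
    if np.any(b <= 0):
        raise ValueError("bleach curve must be positive after dark correction")
    return (raw - opp) / b


# ---------------------------------------------------------------------------
# turnover and speed fits


@dataclass(frozen=True)
class TurnoverFit:
    """Dual-exponential turnover parameters (rates in min⁻¹)."""

    amp_slow: float
    k_slow: float
    amp_fast: float
    k_fast: float
    valid: bool = True
    flags: tuple[str, ...] = ()

    @property
    def slow_fraction(self) -> float:
        return self.amp_slow / (self.amp_slow + self.amp_fast)

    @property
    def lifetime_slow_min(self) -> float:
        return 1.0 / self.k_slow

    @property
    def lifetime_fast_min(self) -> float:
        return 1.0 / self.k_fast


def dual_exponential(t, a_s, k_s, a_f, k_f):
    return a_s * np.exp(-k_s * t) + a_f * np.exp(-k_f * t)


def fit_turnover(
    t_min: np.ndarray,
    heights: np.ndarray,
    min_points: int = 10,
) -> TurnoverFit:
    """Fit corrected peak heights vs time (min) to a dual exponential.

    Initialization is staged to avoid local minima: a log-linear fit of
    the late tail seeds the slow component, then the early residual
    seeds the fast one.  Fits with k_fast < 2·k_slow are flagged
    ("identifiability") as the two components are not separable; runs
    shorter than ~2 slow lifetimes are flagged ("short_record").
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(heights, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < min_points:
        return TurnoverFit(np.nan, np.nan, np.nan, np.nan, valid=False, flags=("too_few_points",))
    order = np.argsort(t)
    t, y = t[order], y[order]

    # stage 1: slow component from the late tail (last half, positive values)
    tail = slice(len(t) // 2, None)
    yt = np.clip(y[tail], 1e-12, None)
    slope, intercept = np.polyfit(t[tail], np.log(yt), 1)
    k_s0 = float(np.clip(-slope, 1e-3, 50.0))
    a_s0 = float(np.clip(np.exp(intercept), 1e-9, None))
    # stage 2: fast component from the early residual
    resid = y - a_s0 * np.exp(-k_s0 * t)
    early = resid[: max(3, len(t) // 4)]
    a_f0 = float(np.clip(early[0] if early[0] > 0 else np.max(resid), 1e-9, None))
    k_f0 = max(10.0 * k_s0, 1.0)

    try:
        popt, _ = optimize.curve_fit(
            dual_exponential,
            t,
            y,
            p0=[a_s0, k_s0, a_f0, k_f0],
            bounds=([0, 1e-4, 0, 1e-4], [np.inf, 100, np.inf, 100]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError) as e:
        log.warning("dual-exponential fit failed: %s", e)
        return TurnoverFit(np.nan, np.nan, np.nan, np.nan, valid=False, flags=("no_convergence",))
    a1, k1, a2, k2 = popt
    # order components: slow = smaller rate
    if k1 <= k2:
        a_s, k_s, a_f, k_f = a1, k1, a2, k2
    else:
        a_s, k_s, a_f, k_f = a2, k2, a1, k1
    flags = []
    if k_f < 2 * k_s:
        flags.append("identifiability")
    if t[-1] - t[0] < 2.0 / max(k_s, 1e-9):
        flags.append("short_record")
    if k_s <= 2e-4 or k_f >= 99.0:
        flags.append("boundary")
    return TurnoverFit(
        amp_slow=float(a_s),
        k_slow=float(k_s),
        amp_fast=float(a_f),
        k_fast=float(k_f),
        valid=True,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class SpeedFit:
    """Linear fit of peak center vs time: poleward speed (µm/min) > 0."""

    speed_um_per_min: float
    initial_position_um: float
    stderr: float
    n_frames: int
    valid: bool = True


def fit_speed(t_min: np.ndarray, centers_um: np.ndarray, min_frames: int = 5) -> SpeedFit:
    """Ordinary least squares of peak center (distance from pole) vs time.

    Poleward motion (decreasing distance) is reported as positive speed.
    The initial position is the fitted center at t = 0 (activation).
    Flagged invalid below ``min_frames`` valid frames.
    """
    t = np.asarray(t_min, dtype=float)
    c = np.asarray(centers_um, dtype=float)
    ok = np.isfinite(t) & np.isfinite(c)
    t, c = t[ok], c[ok]
    if len(t) < min_frames:
        return SpeedFit(np.nan, np.nan, np.nan, len(t), valid=False)
    A = np.vstack([t, np.ones_like(t)]).T
    coef, res, *_ = np.linalg.lstsq(A, c, rcond=None)
    slope, intercept = coef
    dof = len(t) - 2
    if dof > 0 and len(res):
        se = float(np.sqrt(res[0] / dof / np.sum((t - t.mean()) ** 2)))
    else:
        se = np.nan
    return SpeedFit(
        speed_um_per_min=float(-slope),
        initial_position_um=float(intercept),
        stderr=se,
        n_frames=len(t),
    )


@dataclass(frozen=True)
class MovieAnalysis:
    speed: SpeedFit
    turnover: TurnoverFit
    centers_um: np.ndarray
    heights: np.ndarray
    corrected_heights: np.ndarray
    times_min: np.ndarray


def analyze_movie(
    movie: PhotoconversionMovie,
    band_halfwidth: int = 15,
    window: int = 5,
    bleach: np.ndarray | float = 1.0,
    sub_band_um: Optional[float] = None,
    pole: int = 0,
) -> MovieAnalysis:
    """Full analysis chain: line profiles → peak track → speed + turnover."""
    frames = range(movie.activation_frame, movie.n_frames)
    t = movie.times_min[movie.activation_frame :]
    centers, heights, opp = [], [], []
    prev = None
    p0, p1 = movie.pole_tracks[movie.activation_frame]
    spindle_len = float(np.linalg.norm(p1 - p0)) * movie.pixel_size
    for f in frames:
        prof = extract_line_profile(
            movie, f, band_halfwidth=band_halfwidth, sub_band_um=sub_band_um, pole=pole
        )
        pk = fit_peak(prof, previous_center=prev, window=window)
        if pk.valid:
            prev = pk.center_um
            ob = fit_opposite_peak(prof, pk.center_um, spindle_len, window=window)
            centers.append(pk.center_um)
            heights.append(pk.height)
            opp.append(ob.height if ob.valid else 0.0)
        else:
            centers.append(np.nan)
            heights.append(np.nan)
            opp.append(np.nan)
    centers = np.asarray(centers)
    heights = np.asarray(heights)
    opp = np.asarray(opp)
    b = np.broadcast_to(np.asarray(bleach, dtype=float), heights.shape)
    corrected = np.where(
        np.isfinite(heights), correct_height(np.nan_to_num(heights), np.nan_to_num(opp), b), np.nan
    )
    return MovieAnalysis(
        speed=fit_speed(t, centers),
        turnover=fit_turnover(t, corrected),
        centers_um=centers,
        heights=heights,
        corrected_heights=corrected,
        times_min=t,
    )


# ---------------------------------------------------------------------------
# forward simulation


@dataclass(frozen=True)
class ImagingConfig:
    """Rendering parameters for simulated photoconversion movies."""

    pixel_size: float = 0.1  # µm / px
    frame_interval: float = 5.0  # s
    n_frames: int = 30
    gamma: float = 1.0  # modified-Cauchy half-width, µm
    cauchy_power: float = 1.0
    sigma_z: float = 1.0  # axial activation width, µm (3D mode)
    z_slice: float = 1.0  # rendered confocal slice thickness, µm (3D mode)
    blur_px: float = 1.0  # optical blur of rendered frames
    mark_spacing: float = 0.05  # tubulin sampling along KMTs, µm
    nonkmt_amplitude: float = 0.0  # immobile fast pool amplitude (0 disables)
    nonkmt_rate: float = 1.0 / 0.26  # min⁻¹, fast-pool turnover
    noise_sd: float = 0.0
    dt: float = 0.01  # advection step, min


def simulate_photoconversion(
    pop_snapshot: Snapshot,
    streamlines: Sequence[Streamline],
    speed: SpeedProfile,
    activation_x: float,
    imaging: ImagingConfig,
    detachment_rate: float,
    rng: Optional[np.random.Generator] = None,
    pin_floor: float = 0.0,
) -> PhotoconversionMovie:
    """Render a photoconversion movie from a simulated KMT population.

    A line at spindle-frame position ``activation_x`` (µm, in the
    snapshot's 2D plane; the line runs perpendicular to the spindle
    axis) marks tubulin on every live KMT with the modified-Cauchy
    profile evaluated at each tubulin sample's distance from the line.
    Marks advect poleward at the tubulin speed v_tub of their KMT,
    vanish on crossing the (treadmilling) minus end, and disappear when
    their KMT detaches (exponential lifetime, rate ``detachment_rate``).
    An optional immobile fast-turnover pool adds the non-KMT
    contribution.  Pole markers follow the streamline poles.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    snap = pop_snapshot
    n = snap.n_kmts
    if n == 0:
        raise ValueError("empty population")

    # geometry of the rendered frame (spindle frame, µm)
    all_pts = np.vstack([sl.points for sl in streamlines])
    x_lo, y_lo = all_pts.min(axis=0) - 0.5
    x_hi, y_hi = all_pts.max(axis=0) + 0.5
    if not (x_lo <= activation_x <= x_hi):
        raise ValueError(f"activation line x={activation_x} outside the spindle")
    W = int(np.ceil((x_hi - x_lo) / imaging.pixel_size))
    H = int(np.ceil((y_hi - y_lo) / imaging.pixel_size))

    # per-KMT mark arrays
    mark_sigma: list[np.ndarray] = []
    mark_w: list[np.ndarray] = []
    for i in range(n):
        sl = streamlines[snap.streamline_idx[i]]
        s0, s1 = snap.s_minus[i], snap.s_kin[i]
        if s1 <= s0:
            mark_sigma.append(np.empty(0))
            mark_w.append(np.empty(0))
            continue
        ss = np.arange(s0, s1 + imaging.mark_spacing / 2, imaging.mark_spacing)
        pts = np.atleast_2d(sl.point_at(ss))
        w = modified_cauchy(pts[:, 0] - activation_x, imaging.gamma, imaging.cauchy_power)
        keep = w > 1e-4
        mark_sigma.append(ss[keep])
        mark_w.append(np.full(keep.sum(), imaging.mark_spacing) * w[keep])
    s_minus = snap.s_minus.copy()
    death = rng.exponential(1.0 / detachment_rate, n)  # remaining lifetimes
    alive = np.ones(n, dtype=bool)

    # immobile fast pool: the activation profile painted on all streamline
    # tubulin, decaying at the fast rate
    bg = np.zeros((H, W))
    if imaging.nonkmt_amplitude > 0:
        for sl in streamlines:
            ss = np.arange(0.0, sl.s_max, imaging.mark_spacing)
            pts = np.atleast_2d(sl.point_at(ss))
            w = imaging.nonkmt_amplitude * modified_cauchy(
                pts[:, 0] - activation_x, imaging.gamma, imaging.cauchy_power
            )
            _splat(bg, pts, w * imaging.mark_spacing, x_lo, y_lo, imaging.pixel_size)

    frame_dt_min = imaging.frame_interval / 60.0
    steps_per_frame = max(1, int(round(frame_dt_min / imaging.dt)))
    dt = frame_dt_min / steps_per_frame

    frames = np.zeros((imaging.n_frames, H, W))
    # pole markers: mean streamline origin per pole label; a missing pole
    # (half-spindle stack) is marked at the far streamline ends instead
    origins = {p: [] for p in (0, 1)}
    far_ends = []
    for sl in streamlines:
        origins[sl.pole].append(sl.points[0])
        far_ends.append(sl.points[-1])
    pole_xy = np.zeros((2, 2))
    for p in (0, 1):
        if origins[p]:
            pole_xy[p] = np.mean(origins[p], axis=0)
        else:
            pole_xy[p] = np.mean(far_ends, axis=0)
    if pole_xy[0, 0] > pole_xy[1, 0]:
        pole_xy = pole_xy[::-1]
    poles_px = (pole_xy - np.array([x_lo, y_lo])) / imaging.pixel_size

    t = 0.0
    for f in range(imaging.n_frames):
        img = np.zeros((H, W))
        for i in range(n):
            if not alive[i] or len(mark_sigma[i]) == 0:
                continue
            sl = streamlines[snap.streamline_idx[i]]
            pts = np.atleast_2d(sl.point_at(mark_sigma[i]))
            _splat(img, pts, mark_w[i], x_lo, y_lo, imaging.pixel_size)
        img += bg * np.exp(-imaging.nonkmt_rate * t)
        if imaging.blur_px > 0:
            img = ndimage.gaussian_filter(img, imaging.blur_px)
        if imaging.noise_sd > 0:
            img = img + rng.normal(0.0, imaging.noise_sd, img.shape)
        frames[f] = img

        # advance to the next frame (vectorized over KMTs; marks on one
        # KMT shift rigidly so the per-KMT shift is accumulated and
        # applied once per frame, with minus-end trimming afterwards)
        shift = np.zeros(n)
        for _ in range(steps_per_frame):
            v = speed.v_at(s_minus)
            vt = speed.v_tub_at(s_minus)
            shift += np.where(alive, vt * dt, 0.0)
            s_minus = np.where(alive, np.maximum(s_minus - v * dt, pin_floor), s_minus)
            t += dt
        alive &= death > t
        for i in range(n):
            if not alive[i] or len(mark_sigma[i]) == 0:
                continue
            mark_sigma[i] = mark_sigma[i] - shift[i]
            keep = mark_sigma[i] >= s_minus[i]
            if not np.all(keep):
                mark_sigma[i] = mark_sigma[i][keep]
                mark_w[i] = mark_w[i][keep]

    tracks = np.broadcast_to(poles_px[None, :, :], (imaging.n_frames, 2, 2)).copy()
    return PhotoconversionMovie(
        frames=frames,
        pixel_size=imaging.pixel_size,
        frame_interval=imaging.frame_interval,
        pole_tracks=tracks,
        activation_frame=0,
        activation_line=np.array(
            [
                [(activation_x - x_lo) / imaging.pixel_size, 0.0],
                [(activation_x - x_lo) / imaging.pixel_size, H - 1.0],
            ]
        ),
        meta={"activation_x_um": float(activation_x)},
    )


def _splat(
    img: np.ndarray,
    pts: np.ndarray,
    w: np.ndarray,
    x_lo: float,
    y_lo: float,
    pixel_size: float,
) -> None:
    """Bilinear deposition of weighted points into an image (in place)."""
    fx = (pts[:, 0] - x_lo) / pixel_size
    fy = (pts[:, 1] - y_lo) / pixel_size
    i0 = np.floor(fx).astype(int)
    j0 = np.floor(fy).astype(int)
    tx, ty = fx - i0, fy - j0
    H, W = img.shape
    for dj, di, ww in (
        (0, 0, (1 - tx) * (1 - ty)),
        (0, 1, tx * (1 - ty)),
        (1, 0, (1 - tx) * ty),
        (1, 1, tx * ty),
    ):
        jj, ii = j0 + dj, i0 + di
        ok = (ii >= 0) & (ii < W) & (jj >= 0) & (jj < H)
        np.add.at(img, (jj[ok], ii[ok]), w[ok] * ww[ok])
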