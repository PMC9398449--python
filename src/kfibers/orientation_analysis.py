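"""Orientation statistics of spindle microtubules.

Microtubule orientations are nematic (headless): an angle θ and θ + π
describe the same physical orientation, so all circular statistics run
in the doubled-angle representation.  The mean orientation of a set of
angles is ⟨θ⟩ = arg(⟨e^{2iθ}⟩)/2 and the scalar nematic order parameter

    S = ⟨(3 cos²(θ − ⟨θ⟩) − 1) / 2⟩

is 1 for perfectly aligned microtubules, 0 for isotropically ordered
ones and −0.5 for alignment perpendicular to the mean.  This is the
uniaxial (3D-normalized) estimator applied to in-plane projected
angles; the purely 2D estimator ⟨cos 2(θ − ⟨θ⟩)⟩ is available for
comparison via ``estimator="2d"``.

Spatially resolved analyses bin 0.1 µm microtubule segments into a
(spindle axis × radial axis) grid; whole spindles are registered onto a
common frame by rescaling the axis with the pole–pole distance and the
radial direction with the width of an ellipse fitted to the density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from kfibers import nematic_field
from kfibers.spindle_io import OrientationMap, SpindleReconstruction, to_spindle_frame

log = logging.getLogger(__name__)


def wrap_nematic(theta: np.ndarray) -> np.ndarray:
    """Map angles into the nematic fundamental domain (−π/2, π/2]."""
    return -(np.mod(-np.asarray(theta) + np.pi / 2, np.pi) - np.pi / 2)


def resample_polyline(points: np.ndarray, segment_len: float) -> np.ndarray:
    """Resample a polyline at fixed arc-length intervals (endpoints kept)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return points[:1]
    n = max(1, int(np.ceil(total / segment_len)))
    si = np.linspace(0.0, total, n + 1)
    out = np.stack([np.interp(si, s, points[:, k]) for k in range(points.shape[1])], axis=1)
    return out


def segment_angles(
    rec: SpindleReconstruction,
    cls: str | None = None,
    segment_len: float = 0.1,
) -> pd.DataFrame:
    """Projected in-plane angles of short microtubule segments.

    Each microtubule is resampled into ~``segment_len`` µm segments in
    the spindle frame; the angle of each segment in the projected
    (axis, y) plane is reported modulo π together with the segment
    midpoint and length.  Degenerate zero-length segments are skipped
    (logged).  ``cls`` optionally restricts to "KMT" or "non-KMT".
    """
    if segment_len <= 0:
        raise ValueError("segment_len must be positive")
    rows = []
    for i, mt in enumerate(rec.mts):
        if cls is not None and mt.cls != cls:
            continue
        pts = to_spindle_frame(mt.points, rec.poles)
        pts = resample_polyline(pts, segment_len)
        d = np.diff(pts, axis=0)
        lens = np.linalg.norm(d, axis=1)
        good = lens > 1e-12
        if not np.all(good):
            log.debug("MT %s: skipped %d zero-length segments", mt.mt_id, (~good).sum())
        d, lens = d[good], lens[good]
        mids = 0.5 * (pts[:-1] + pts[1:])[good]
        # projection into the (axis, y) plane: drop z
        ang = wrap_nematic(np.arctan2(d[:, 1], d[:, 0]))
        axial_frac = np.abs(d[:, 0]) / lens
        for m, a, L, af in zip(mids, ang, lens, axial_frac):
            rows.append(
                {
                    "mt_id": mt.mt_id if mt.mt_id is not None else i,
                    "x": m[0],
                    "y": m[1],
                    "z": m[2],
                    "angle": a,
                    "length": L,
                    "axial_fraction": af,
                }
            )
    return pd.DataFrame(
        rows, columns=["mt_id", "x", "y", "z", "angle", "length", "axial_fraction"]
    )


def mean_orientation(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Nematic circular mean ⟨θ⟩ = arg(⟨e^{2iθ}⟩)/2 in (−π/2, π/2].

    Raises ``ValueError`` on an empty set; a perfectly balanced set
    (resultant length ~0, e.g. equal weight at Δθ = ±45°) has no defined
    mean and also raises.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle set")
    w = np.ones_like(angles) if weights is None else np.asarray(weights, dtype=float)
    z = np.sum(w * np.exp(2j * angles)) / np.sum(w)
    if np.abs(z) < 1e-12:
        raise ValueError("mean orientation undefined: zero resultant (balanced set)")
    th = 0.5 * np.angle(z)
    # np.angle yields (-pi, pi]; θ in (-pi/2, pi/2]
    return float(th)


def order_parameter(
    angles: np.ndarray,
    weights: np.ndarray | None = None,
    mean: float | None = None,
    estimator: str = "uniaxial",
) -> float:
    """Scalar nematic order parameter about the mean orientation.

    ``estimator="uniaxial"`` (default): S = ⟨(3 cos²Δ − 1)/2⟩, the
    uniaxial convention (1 aligned, 0 isotropic in 3D, −0.5
    perpendicular).  ``estimator="2d"``: S = ⟨cos 2Δ⟩ (0 for in-plane
    isotropic angles).  Weighted by segment length when given.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle set")
    w = np.ones_like(angles) if weights is None else np.asarray(weights, dtype=float)
    if mean is None:
        mean = mean_orientation(angles, w)
    delta = angles - mean
    if estimator == "uniaxial":
        vals = 0.5 * (3.0 * np.cos(delta) ** 2 - 1.0)
    elif estimator == "2d":
        vals = np.cos(2.0 * delta)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return float(np.sum(w * vals) / np.sum(w))


@dataclass(frozen=True)
class BinnedOrientationField:
    """Per-bin mean angle, order parameter and segment count on an
    (axis, radial) grid with square ``bin_size`` bins.

    ``x_edges``/``y_edges`` are the bin edges (µm, spindle frame);
    ``count == 0`` flags empty bins (angle/S are NaN there).
    """

    angle: np.ndarray
    S: np.ndarray
    count: np.ndarray
    weight: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def occupied(self) -> np.ndarray:
        return self.count > 0

    def to_orientation_map(self) -> OrientationMap:
        return OrientationMap(
            angle=np.where(self.count > 0, np.nan_to_num(self.angle), 0.0),
            weight=np.where(self.count > 0, self.weight, 0.0),
            bin_size=self.bin_size,
            origin=(float(self.x_centers[0]), float(self.y_centers[0])),
        )


def _bin_segments(
    x: np.ndarray,
    y: np.ndarray,
    angle: np.ndarray,
    weight: np.ndarray,
    bin_size: float,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    estimator: str = "uniaxial",
) -> BinnedOrientationField:
    x_edges = np.arange(x_range[0], x_range[1] + bin_size, bin_size)
    y_edges = np.arange(y_range[0], y_range[1] + bin_size, bin_size)
    shape = (len(y_edges) - 1, len(x_edges) - 1)
    ix = np.clip(np.digitize(x, x_edges) - 1, 0, shape[1] - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, shape[0] - 1)
    inb = (x >= x_edges[0]) & (x <= x_edges[-1]) & (y >= y_edges[0]) & (y <= y_edges[-1])
    ix, iy = ix[inb], iy[inb]
    angle, weight = angle[inb], weight[inb]

    flat = iy * shape[1] + ix
    nbins = shape[0] * shape[1]
    wsum = np.bincount(flat, weights=weight, minlength=nbins)
    csum = np.bincount(flat, weights=weight * np.cos(2 * angle), minlength=nbins)
    ssum = np.bincount(flat, weights=weight * np.sin(2 * angle), minlength=nbins)
    count = np.bincount(flat, minlength=nbins)

    mean = 0.5 * np.arctan2(ssum, csum)
    # order parameter about the per-bin mean
    if estimator == "uniaxial":
        # ⟨(3cos²Δ − 1)/2⟩ = 3/4⟨cos 2Δ⟩ + 1/4 ; ⟨cos 2Δ⟩ = |⟨e^{2iθ}⟩| when
        # Δ is measured from the circular mean
        r = np.hypot(csum, ssum) / np.where(wsum > 0, wsum, 1.0)
        S = 0.75 * r + 0.25
    else:
        r = np.hypot(csum, ssum) / np.where(wsum > 0, wsum, 1.0)
        S = r
    empty = count == 0
    mean[empty] = np.nan
    S[empty] = np.nan
    return BinnedOrientationField(
        angle=mean.reshape(shape),
        S=S.reshape(shape),
        count=count.reshape(shape),
        weight=wsum.reshape(shape),
        x_edges=x_edges,
        y_edges=y_edges,
        bin_size=bin_size,
    )


def rotational_average(
    rec: SpindleReconstruction,
    cls: str | None = None,
    bin_size: float = 0.1,
    rotation_step: float = np.pi / 10,
    segment_len: float = 0.1,
    estimator: str = "uniaxial",
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> BinnedOrientationField:
    """Rotationally averaged binned orientation field of a reconstruction.

    The 3D segment cloud is rotated about the spindle axis in
    ``rotation_step`` increments over a full turn, projected into the
    (axis, y) plane after each rotation and accumulated into
    ``bin_size`` µm bins, producing an axisymmetric average (each
    segment contributes one copy per rotation).
    """
    seg = segment_angles(rec, cls=cls, segment_len=segment_len)
    if seg.empty:
        raise ValueError("no segments to average")
    n_rot = int(round(2 * np.pi / rotation_step))
    y, z = seg["y"].to_numpy(), seg["z"].to_numpy()
    x = seg["x"].to_numpy()
    # reconstruct in-plane 3D direction from angle + axial fraction is
    # lossy; rotate the original 3D segment vectors instead
    all_x, all_y, all_ang, all_w = [], [], [], []
    # recompute segment vectors in the spindle frame once
    for phi in (np.arange(n_rot) * rotation_step):
        c, s = np.cos(phi), np.sin(phi)
        y_r = c * y - s * z
        # angle after rotation: need the rotated direction vector; store
        # via the original 3D directions below.
        all_x.append(x)
        all_y.append(y_r)
    # direction vectors per segment
    seg_dirs = _segment_direction_table(rec, cls, segment_len)
    dx, dy, dz = seg_dirs.T
    for k, phi in enumerate(np.arange(n_rot) * rotation_step):
        c, s = np.cos(phi), np.sin(phi)
        dyr = c * dy - s * dz
        ang = wrap_nematic(np.arctan2(dyr, dx))
        all_ang.append(ang)
        all_w.append(seg["length"].to_numpy())
    X = np.concatenate(all_x)
    Y = np.concatenate(all_y)
    A = np.concatenate(all_ang)
    W = np.concatenate(all_w)
    pad = bin_size
    if x_range is None:
        x_range = (X.min() - pad, X.max() + pad)
    if y_range is None:
        y_range = (Y.min() - pad, Y.max() + pad)
    return _bin_segments(X, Y, A, W, bin_size, x_range, y_range, estimator=estimator)


def _segment_direction_table(
    rec: SpindleReconstruction, cls: str | None, segment_len: float
) -> np.ndarray:
    dirs = []
    for mt in rec.mts:
        if cls is not None and mt.cls != cls:
            continue
        pts = to_spindle_frame(mt.points, rec.poles)
        pts = resample_polyline(pts, segment_len)
        d = np.diff(pts, axis=0)
        lens = np.linalg.norm(d, axis=1)
        good = lens > 1e-12
        dirs.append(d[good] / lens[good, None])
    return np.vstack(dirs) if dirs else np.zeros((0, 3))


# ---------------------------------------------------------------------------
# registration


def fit_density_ellipse(
    weight: np.ndarray,
    x_centers: np.ndarray,
    y_centers: np.ndarray,
    quantile: float = 0.5,
) -> tuple[float, float, float, float]:
    """Ellipse (cx, cy, a, b) fitted to a thresholded density image.

    The density is thresholded at ``quantile`` of its nonzero values and
    the ellipse recovered from the second moments of the mask (a robust
    stand-in for perimeter least squares).  Raises ``ValueError`` if the
    threshold yields no closed region.
    """
    w = np.nan_to_num(np.asarray(weight, dtype=float))
    nz = w[w > 0]
    if nz.size == 0:
        raise ValueError("empty density: ellipse fit failed")
    thr = np.quantile(nz, quantile)
    mask = w >= thr
    if mask.sum() < 5:
        raise ValueError("threshold yields no closed region: ellipse fit failed")
    X, Y = np.meshgrid(x_centers, y_centers)
    cx, cy = X[mask].mean(), Y[mask].mean()
    # second moments of a filled ellipse: var_x = a²/4, var_y = b²/4
    a = 2.0 * X[mask].std()
    b = 2.0 * Y[mask].std()
    return float(cx), float(cy), float(a), float(b)


def register_spindles(
    fields: list[BinnedOrientationField],
    target_pole_distance: float | None = None,
    target_width: float | None = None,
    ellipse_quantile: float = 0.5,
) -> BinnedOrientationField:
    """Rescale binned fields to a common frame and average them.

    Each field is affinely rescaled along the spindle axis so all items
    share the same axis extent (by default the first item's) and along
    the radial axis so the widths of density-fitted ellipses agree, then
    averaged in the doubled-angle representation, weighted by density.
    Items whose ellipse fit fails are skipped with a warning.  A single
    item is returned under the identity transform.
    """
    if not fields:
        raise ValueError("no fields to register")
    kept, scales = [], []
    for i, f in enumerate(fields):
        try:
            cx, cy, a, b = fit_density_ellipse(
                f.weight, f.x_centers, f.y_centers, ellipse_quantile
            )
        except ValueError as e:
            log.warning("skipping item %d: %s", i, e)
            continue
        kept.append(f)
        scales.append((cx, cy, a, b))
    if not kept:
        raise ValueError("all ellipse fits failed")
    ref_cx, ref_cy, ref_a, ref_b = scales[0]
    if target_pole_distance is not None:
        ref_a = target_pole_distance / 2
    if target_width is not None:
        ref_b = target_width / 2
    base = kept[0]
    if len(kept) == 1 and target_pole_distance is None and target_width is None:
        return base

    # accumulate into the reference grid
    shape = base.angle.shape
    csum = np.zeros(shape)
    ssum = np.zeros(shape)
    wsum = np.zeros(shape)
    count = np.zeros(shape, dtype=int)
    Xr, Yr = np.meshgrid(base.x_centers, base.y_centers)
    for f, (cx, cy, a, b) in zip(kept, scales):
        # map reference coords into this item's frame
        xs = (Xr - ref_cx) * (a / ref_a) + cx
        ys = (Yr - ref_cy) * (b / ref_b) + cy
        ix = np.clip(
            np.digitize(xs.ravel(), f.x_edges) - 1, 0, len(f.x_centers) - 1
        ).reshape(shape)
        iy = np.clip(
            np.digitize(ys.ravel(), f.y_edges) - 1, 0, len(f.y_centers) - 1
        ).reshape(shape)
        ang = f.angle[iy, ix]
        w = f.weight[iy, ix]
        ok = np.isfinite(ang) & (w > 0)
        # angles are scale-invariant under the pure axis/radial rescale
        # only if a/ref_a == b/ref_b; otherwise shear the angle:
        kx, ky = a / ref_a, b / ref_b
        tan_src = np.tan(ang[ok])
        ang_ref = np.arctan(tan_src * kx / ky)
        csum[ok] += w[ok] * np.cos(2 * ang_ref)
        ssum[ok] += w[ok] * np.sin(2 * ang_ref)
        wsum[ok] += w[ok]
        count[ok] += 1
    mean = 0.5 * np.arctan2(ssum, csum)
    r = np.hypot(csum, ssum) / np.where(wsum > 0, wsum, 1.0)
    S = 0.75 * r + 0.25
    empty = count == 0
    mean[empty] = np.nan
    S[empty] = np.nan
    return BinnedOrientationField(
        angle=mean,
        S=S,
        count=count,
        weight=wsum / np.maximum(count, 1),
        x_edges=base.x_edges,
        y_edges=base.y_edges,
        bin_size=base.bin_size,
    )


# ---------------------------------------------------------------------------
# geometry fitting


def _model_angle_chi2(
    field: BinnedOrientationField,
    geom: nematic_field.SpindleGeometry,
    solver_spacing: float,
) -> float:
    """Density-weighted χ² between measured and model angles over occupied bins."""
    try:
        sol = nematic_field.solve_director(geom, spacing=solver_spacing, tol=1e-5)
    except (ValueError, nematic_field.ConvergenceError):
        return np.inf
    occ = field.occupied() & np.isfinite(field.angle)
    X, Y = np.meshgrid(field.x_centers, field.y_centers)
    pts = np.stack([X[occ], Y[occ]], axis=1)
    ins = geom.inside(pts[:, 0], pts[:, 1])
    if ins.sum() < 10:
        return np.inf
    model = sol.angle_at(pts[ins])
    meas = field.angle[occ][ins]
    w = field.weight[occ][ins]
    d = wrap_nematic(meas - model)
    return float(np.sum(w * d**2) / np.sum(w))


def fit_geometry(
    field: BinnedOrientationField,
    solver_spacing: float = 0.25,
    defect_radius0: float = 0.5,
) -> tuple[nematic_field.SpindleGeometry, float]:
    """Two-stage fit of the spindle geometry to a binned orientation field.

    Stage 1 fits the elliptical boundary (center, height, width) with the
    two +1 defects pinned at the ellipse edge on the axis; stage 2 fixes
    the boundary and fits the defect positions along the axis and the
    defect radius.  The χ² statistic is the density-weighted squared
    angular deviation between measured and model angles over occupied
    bins.  Returns the best geometry and its χ².
    """
    if int(field.occupied().sum()) < 10:
        raise ValueError("need >= 10 occupied bins to fit a geometry")
    cx0, cy0, a0, b0 = fit_density_ellipse(
        np.where(field.occupied(), np.maximum(field.weight, 1e-12), 0.0),
        field.x_centers,
        field.y_centers,
    )

    def make_geom(cx, cy, a, b, dx0, dx1, rd):
        return nematic_field.SpindleGeometry(
            a=a, b=b, defect_x=(dx0, dx1), defect_radius=rd, center=(cx, cy)
        )

    # --- stage 1: boundary, defects pinned near the ellipse vertices
    def cost1(p):
        cx, cy, a, b = p
        if a <= 2 * solver_spacing or b <= 2 * solver_spacing or a <= b * 0.2:
            return np.inf
        edge = a - max(defect_radius0, 2 * solver_spacing) - solver_spacing
        if edge <= 0:
            return np.inf
        try:
            g = make_geom(cx, cy, a, b, -edge, edge, max(defect_radius0, 1.5 * solver_spacing))
        except ValueError:
            return np.inf
        return _model_angle_chi2(field, g, solver_spacing)

    res1 = optimize.minimize(
        cost1,
        x0=[cx0, cy0, a0, b0],
        method="Nelder-Mead",
        options={"xatol": solver_spacing / 4, "fatol": 1e-5, "maxfev": 120},
    )
    cx, cy, a, b = res1.x

    # --- stage 2: defect positions + radius with boundary fixed
    rd0 = max(defect_radius0, 1.5 * solver_spacing)
    edge0 = a - rd0 - 2 * solver_spacing

    def cost2(p):
        dx0, dx1, rd = p
        if rd < 1.5 * solver_spacing:
            return np.inf
        try:
            g = make_geom(cx, cy, a, b, dx0, dx1, rd)
        except ValueError:
            return np.inf
        return _model_angle_chi2(field, g, solver_spacing)

    res2 = optimize.minimize(
        cost2,
        x0=[-edge0, edge0, rd0],
        method="Nelder-Mead",
        options={"xatol": solver_spacing / 4, "fatol": 1e-5, "maxfev": 120},
    )
    dx0, dx1, rd = res2.x
    if not (np.isfinite(res2.fun) and res2.fun < np.inf):
        raise RuntimeError(f"geometry fit did not converge; last iterate {res2.x}")
    best = make_geom(cx, cy, a, b, dx0, dx1, rd)
    return best, float(res2.fun)


def chi2_at(
    field: BinnedOrientationField,
    geom: nematic_field.SpindleGeometry,
    solver_spacing: float = 0.25,
) -> float:
    """χ² of a given geometry against a binned field (for fit diagnostics)."""
    return _model_angle_chi2(field, geom, solver_spacing)
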