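"""Steady-state nematic director field of the spindle and its streamlines.

In the one-elastic-constant active-liquid-crystal description, the
steady-state orientation field of spindle microtubules obeys the Laplace
equation ∇²n = 0 inside the spindle, with tangential anchoring on the
elliptical spindle boundary and radial anchoring at two +1 aster defects
(the poles).  Because the field is headless (n ≡ −n) the 2D solve
operates on the doubled-angle unit vector (cos 2θ, sin 2θ): each
relaxation sweep replaces a bulk cell by the normalized average of its
four neighbours, which converges to the harmonic map with the imposed
boundary data and is free of angle-wrapping artifacts.

Streamlines — curves everywhere tangent to the director — are the tracks
along which KMTs grow and their minus ends move.  The arc-length
coordinate ``s`` measures distance from the pole (s = 0 at the pole
center) along a streamline.

The solved field depends only on the geometry: there are no material
parameters anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np


class ConvergenceError(RuntimeError):
    """Relaxation failed to reach the requested residual."""

    def __init__(self, msg: str, residual: float):
        super().__init__(msg)
        self.residual = residual


@dataclass(frozen=True)
class SpindleGeometry:
    """Elliptical spindle with two aster defects on the long axis.

    ``a``/``b`` are the semi-axes (µm) along the spindle and radial
    directions; ``defect_x`` holds the two defect-center x coordinates
    (spindle-axis coordinate relative to ``center``); defects are disks
    of ``defect_radius`` µm with radial anchoring.
    """

    a: float
    b: float
    defect_x: tuple[float, float]
    defect_radius: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")
        if self.defect_radius <= 0:
            raise ValueError("defect radius must be positive")
        for dx in self.defect_x:
            if (dx / self.a) ** 2 >= 1.0:
                raise ValueError(f"defect at x={dx} lies outside the ellipse")
        # defect disk must not touch the boundary
        for dx in self.defect_x:
            d_edge = self._distance_to_boundary(dx)
            if self.defect_radius >= d_edge:
                raise ValueError(
                    f"defect radius {self.defect_radius} exceeds distance "
                    f"{d_edge:.3f} from defect at x={dx} to the boundary"
                )

    def _distance_to_boundary(self, dx: float) -> float:
        # conservative estimate: min over sampled boundary points
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        bx, by = self.a * np.cos(t), self.b * np.sin(t)
        return float(np.min(np.hypot(bx - dx, by)))

    @property
    def defect_centers(self) -> np.ndarray:
        cx, cy = self.center
        return np.array([[cx + self.defect_x[0], cy], [cx + self.defect_x[1], cy]])

    def inside(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        return ((x - cx) / self.a) ** 2 + ((y - cy) / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class DirectorField:
    """Solved headless orientation field on a regular 2D grid.

    ``c2``/``s2`` are the (cos 2θ, sin 2θ) planes (NaN outside the
    spindle); ``x``/``y`` the cell-center coordinates.  ``axisymmetric``
    marks a meridional-plane solve (y >= 0 is the cylindrical radius),
    used for 3D analyses.
    """

    c2: np.ndarray
    s2: np.ndarray
    x: np.ndarray
    y: np.ndarray
    geometry: SpindleGeometry
    spacing: float
    residual: float
    axisymmetric: bool = False
    bulk_mask: np.ndarray = dc_field(default=None, repr=False)

    @property
    def theta(self) -> np.ndarray:
        """Director angle in (−π/2, π/2] per cell (NaN outside)."""
        th = 0.5 * np.arctan2(self.s2, self.c2)
        return th

    def angle_at(self, pts: np.ndarray) -> np.ndarray:
        """Director angle at arbitrary points, bilinear in (cos 2θ, sin 2θ)."""
        c2, s2 = self._interp(pts)
        return 0.5 * np.arctan2(s2, c2)

    def direction_at(self, pts: np.ndarray) -> np.ndarray:
        """Headless unit direction at points (sign arbitrary)."""
        th = self.angle_at(np.atleast_2d(pts))
        return np.stack([np.cos(th), np.sin(th)], axis=-1)

    def _interp(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(pts)
        fx = (pts[:, 0] - self.x[0]) / self.spacing
        fy = (pts[:, 1] - self.y[0]) / self.spacing
        i0 = np.clip(np.floor(fx).astype(int), 0, len(self.x) - 2)
        j0 = np.clip(np.floor(fy).astype(int), 0, len(self.y) - 2)
        tx = np.clip(fx - i0, 0.0, 1.0)
        ty = np.clip(fy - j0, 0.0, 1.0)

        def bil(F):
            # grid arrays are indexed [j, i] = [y, x]
            v = (
                F[j0, i0] * (1 - tx) * (1 - ty)
                + F[j0, i0 + 1] * tx * (1 - ty)
                + F[j0 + 1, i0] * (1 - tx) * ty
                + F[j0 + 1, i0 + 1] * tx * ty
            )
            return v

        # NaN-tolerant: fall back to nearest finite neighbour of the 4
        c2 = bil(self.c2)
        s2 = bil(self.s2)
        bad = ~np.isfinite(c2) | ~np.isfinite(s2)
        if np.any(bad):
            for k in np.nonzero(bad)[0]:
                cand = [
                    (self.c2[j, i], self.s2[j, i])
                    for j in (j0[k], j0[k] + 1)
                    for i in (i0[k], i0[k] + 1)
                    if np.isfinite(self.c2[j, i])
                ]
                if cand:
                    c2[k], s2[k] = cand[0]
        n = np.hypot(c2, s2)
        n[n == 0] = 1.0
        return c2 / n, s2 / n


def _boundary_conditions(
    geom: SpindleGeometry, X: np.ndarray, Y: np.ndarray, boundary: str = "tangential"
):
    """Masks and imposed doubled-angle values for boundary/defect cells."""
    cx, cy = geom.center
    inside = geom.inside(X, Y)
    # perimeter cells: inside cells with at least one outside 4-neighbour
    nb_out = np.zeros_like(inside, dtype=bool)
    out = ~inside
    nb_out[1:-1, 1:-1] = (
        out[:-2, 1:-1] | out[2:, 1:-1] | out[1:-1, :-2] | out[1:-1, 2:]
    )
    # cells on the grid edge count as perimeter too
    edge = np.zeros_like(inside, dtype=bool)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    perim = inside & (nb_out | edge)

    # tangential anchoring: tangent of the ellipse through the cell's
    # radial projection, angle = atan2(a²·(-y'), b²·x')? tangent direction
    # of ellipse at parameter t is (-a sin t, b cos t); with
    # (x', y') = (a cos t, b cos t) → t = atan2(y'/b, x'/a).
    xr, yr = X - cx, Y - cy
    t = np.arctan2(yr / geom.b, xr / geom.a)
    if boundary == "tangential":
        theta_tan = np.arctan2(geom.b * np.cos(t), -geom.a * np.sin(t))
    elif boundary == "radial":
        # anchoring along the outward ellipse normal (analytic test case:
        # a disk with radial anchoring everywhere has the pure aster field)
        theta_tan = np.arctan2(yr, xr)
    else:
        raise ValueError(f"unknown boundary anchoring {boundary!r}")

    # defect cells: radial anchoring about each defect center
    theta_def = np.full(X.shape, np.nan)
    defect = np.zeros_like(inside, dtype=bool)
    for dcx, dcy in geom.defect_centers:
        d = np.hypot(X - dcx, Y - dcy)
        m = d <= geom.defect_radius
        theta_def[m] = np.arctan2(Y[m] - dcy, X[m] - dcx)
        defect |= m

    fixed = perim | defect
    theta_fixed = np.where(defect, theta_def, theta_tan)
    return inside, fixed, theta_fixed, defect


def solve_director(
    geom: SpindleGeometry,
    spacing: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 200_000,
    axisymmetric: bool = False,
    boundary: str = "tangential",
) -> DirectorField:
    """Relax the director field to the harmonic map on a regular grid.

    The doubled-angle components are swept with a Jacobi update — each
    bulk cell becomes the normalized average of its four neighbours —
    with tangential boundary cells and radial defect cells re-imposed at
    every iteration.  ``tol`` bounds the final residual, defined as the
    largest magnitude of the component of the discrete Laplacian
    perpendicular to the local director (normalized by 4/spacing²·cell
    value scale), which vanishes for the converged harmonic map.

    With ``axisymmetric=True`` the grid is the meridional (x, ρ)
    half-plane of the rotationally symmetric 3D spindle and the stencil
    carries the cylindrical 1/ρ ∂ρ term; the solved field then describes
    the 3D director in any plane containing the spindle axis.

    The relaxation runs as coarse-to-fine continuation: the problem is
    first solved on grids 4× and 2× coarser (where lattice pinning of
    angle domain walls is weak) and each solution initializes the next
    level.  The finest level starts, absent a coarser one, from the
    bipolar-aster ansatz whose integral curves are circles through both
    defects — an initial state with the correct defect topology.

    Raises :class:`ConvergenceError` with the final residual if
    ``max_iter`` sweeps do not reach ``tol``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if geom.defect_radius / spacing < 1.5:
        raise ValueError(
            f"spacing {spacing} too coarse to resolve defect radius "
            f"{geom.defect_radius} (need >= 3 cells across a defect)"
        )
    init_field: Optional[DirectorField] = None
    for factor in (4, 2):
        coarse = spacing * factor
        if geom.defect_radius / coarse >= 1.5:
            init_field = _relax_level(
                geom, coarse, max(tol, 1e-5), max_iter, axisymmetric, boundary, init_field
            )
    return _relax_level(
        geom, spacing, tol, max_iter, axisymmetric, boundary, init_field
    )


def _relax_level(
    geom: SpindleGeometry,
    spacing: float,
    tol: float,
    max_iter: int,
    axisymmetric: bool,
    boundary: str,
    init_field: Optional[DirectorField] = None,
) -> DirectorField:
    cx, cy = geom.center
    pad = 1.5 * spacing
    x = np.arange(cx - geom.a - pad, cx + geom.a + pad + spacing / 2, spacing)
    if axisymmetric:
        # half-plane: ρ >= 0, with a ghost row handled by symmetry
        y = np.arange(cy, cy + geom.b + pad + spacing / 2, spacing)
    else:
        y = np.arange(cy - geom.b - pad, cy + geom.b + pad + spacing / 2, spacing)
    X, Y = np.meshgrid(x, y)
    inside, fixed, theta_fixed, defect = _boundary_conditions(geom, X, Y, boundary)

    # initial guess with the correct defect topology: the bipolar-aster
    # ansatz whose integral curves are circles through both defects (near
    # each defect it is radial; a uniform start cannot build the required
    # doubled-angle winding and relaxation would pin spurious defects).
    if init_field is not None:
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        th0 = init_field.angle_at(pts).reshape(X.shape)
    else:
        z = (X - cx) + 1j * (Y - cy)
        z1 = complex(geom.defect_x[0], 0.0)
        z2 = complex(geom.defect_x[1], 0.0)
        if abs(z1 - z2) < spacing:
            th0 = np.angle(z - z1 + 1e-30)
        else:
            F = 1.0 / (z - z1 + 1e-30) - 1.0 / (z - z2 + 1e-30)
            th0 = -np.angle(F + 1e-30)
    c2 = np.where(inside, np.cos(2 * th0), np.nan)
    s2 = np.where(inside, np.sin(2 * th0), np.nan)
    c2[fixed] = np.cos(2 * theta_fixed[fixed])
    s2[fixed] = np.sin(2 * theta_fixed[fixed])

    bulk = inside & ~fixed
    bj, bi = np.nonzero(bulk)
    if len(bj) == 0:
        raise ValueError("grid too coarse: no bulk cells")
    # neighbour index arrays (bulk cells never touch the grid edge: the
    # perimeter detector marks edge cells as fixed)
    if axisymmetric:
        rho = Y[bj, bi] - cy
        # cylindrical radial weight: Laplacian = ∂xx + ∂ρρ + (1/ρ)∂ρ.
        # On the axis row, symmetry gives ∂ρρ + (1/ρ)∂ρ → 2 ∂ρρ.
        w_up = np.where(rho > spacing / 2, 1.0 + spacing / (2 * rho), 2.0)
        w_dn = np.where(rho > spacing / 2, 1.0 - spacing / (2 * rho), 0.0)
    else:
        w_up = np.ones(len(bj))
        w_dn = np.ones(len(bj))
    w_l = np.ones(len(bj))
    w_r = np.ones(len(bj))
    wsum = w_up + w_dn + w_l + w_r

    # fill any NaN neighbours of bulk cells (can occur next to masked
    # exterior when perimeter detection and ellipse test disagree by a
    # corner cell): treat them as carrying the tangential angle.
    for F, vals in ((c2, np.cos(2 * theta_fixed)), (s2, np.sin(2 * theta_fixed))):
        for dj, di in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nj, ni = bj + dj, bi + di
            bad = ~np.isfinite(F[nj, ni])
            F[nj[bad], ni[bad]] = vals[nj[bad], ni[bad]]

    # red-black Gauss-Seidel ordering: damps the period-2 checkerboard
    # mode that plain Jacobi leaves neutrally stable
    parity = (bj + bi) % 2
    halves = [np.nonzero(parity == p)[0] for p in (0, 1)]

    residual = np.inf
    for it in range(max_iter):
        residual = 0.0
        for half in halves:
            j, i = bj[half], bi[half]
            avg_c = (
                w_up[half] * c2[j + 1, i]
                + w_dn[half] * c2[j - 1, i]
                + w_l[half] * c2[j, i - 1]
                + w_r[half] * c2[j, i + 1]
            ) / wsum[half]
            avg_s = (
                w_up[half] * s2[j + 1, i]
                + w_dn[half] * s2[j - 1, i]
                + w_l[half] * s2[j, i - 1]
                + w_r[half] * s2[j, i + 1]
            ) / wsum[half]
            norm = np.hypot(avg_c, avg_s)
            norm[norm == 0] = 1.0
            # residual: perpendicular component of the neighbour average —
            # the torque on the cell director; zero at the harmonic-map
            # fixed point.
            perp = np.abs(avg_s * c2[j, i] - avg_c * s2[j, i])
            if len(perp):
                residual = max(residual, float(perp.max()))
            c2[j, i] = avg_c / norm
            s2[j, i] = avg_s / norm
        if residual <= tol:
            break
    else:
        raise ConvergenceError(
            f"director relaxation did not reach tol={tol} in {max_iter} sweeps "
            f"(residual {residual:.3g})",
            residual,
        )
    bulk_mask = bulk
    return DirectorField(
        c2=c2,
        s2=s2,
        x=x,
        y=y,
        geometry=geom,
        spacing=spacing,
        residual=residual,
        axisymmetric=axisymmetric,
        bulk_mask=bulk_mask,
    )


def interior_residual(field: DirectorField) -> float:
    """Recompute the perpendicular-Laplacian residual over bulk cells."""
    c2, s2 = field.c2, field.s2
    bj, bi = np.nonzero(field.bulk_mask)
    avg_c = (c2[bj + 1, bi] + c2[bj - 1, bi] + c2[bj, bi - 1] + c2[bj, bi + 1]) / 4
    avg_s = (s2[bj + 1, bi] + s2[bj - 1, bi] + s2[bj, bi - 1] + s2[bj, bi + 1]) / 4
    perp = np.abs(avg_s * c2[bj, bi] - avg_c * s2[bj, bi])
    return float(perp.max())


@dataclass(frozen=True)
class Streamline:
    """A director-field streamline from a point down to a pole.

    ``points`` run from the pole (defect center) outward; ``s`` is the
    arc-length coordinate per point with s = 0 at the pole center.
    """

    points: np.ndarray  # (n, 2), ordered pole → outward
    s: np.ndarray  # (n,), strictly increasing, s[0] = 0 at the pole
    pole: int

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Interpolate the 2D position at arc-length coordinate(s) s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        px = np.interp(s, self.s, self.points[:, 0])
        py = np.interp(s, self.s, self.points[:, 1])
        out = np.stack([px, py], axis=-1)
        return out if out.shape[0] > 1 else out[0]

    def tangent_at(self, s: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.s, s), 1, len(self.s) - 1))
        d = self.points[i] - self.points[i - 1]
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([1.0, 0.0])

    @property
    def s_max(self) -> float:
        return float(self.s[-1])


def trace_streamline(
    field: DirectorField,
    start: np.ndarray,
    target_pole: int,
    step: Optional[float] = None,
    max_steps: int = 100_000,
) -> Streamline:
    """Integrate the director field from ``start`` to the target pole.

    Midpoint (RK2) integration of the headless tangent; at each step the
    orientation sign is chosen to reduce the distance to the target
    pole's defect center.  Integration stops on entering the defect
    disk; the returned streamline is ordered pole → outward with
    ``s[0] = 0`` at the pole center (the path through the defect disk is
    taken as radial, contributing the distance from the entry point to
    the center).

    Raises ``RuntimeError`` if the trajectory leaves the ellipse, which
    flags inconsistent geometry or boundary conditions.
    """
    geom = field.geometry
    if step is None:
        step = field.spacing / 2
    start = np.asarray(start, dtype=float)
    if not geom.inside(np.array(start[0]), np.array(start[1])):
        raise ValueError(f"start point {start} outside the spindle ellipse")
    pole_c = geom.defect_centers[target_pole]

    pts = [start.copy()]
    p = start.copy()
    p_check = p.copy()
    center = np.asarray(geom.center, dtype=float)
    inward = center - pole_c  # axis direction from this pole toward the equator
    for it in range(max_steps):
        if np.hypot(*(p - pole_c)) <= geom.defect_radius:
            break
        # entering the polar cap behind the defect counts as arrival at
        # the pole region (edge streamlines funnel around the defect rim)
        if np.dot(p - pole_c, inward) < 0:
            break
        # stall detection: trajectories entering the frustrated zone
        # between a defect and the adjacent boundary oscillate in place;
        # terminate there and connect radially to the pole.
        if it % 50 == 49:
            if np.linalg.norm(p - p_check) < step:
                break
            p_check = p.copy()
        d1 = field.direction_at(p)[0]
        to_pole = pole_c - p
        if np.dot(d1, to_pole) < 0:
            d1 = -d1
        mid = p + 0.5 * step * d1
        d2 = field.direction_at(mid)[0]
        if np.dot(d2, d1) < 0:
            d2 = -d2
        p_new = p + step * d2
        if not geom.inside(np.array(p_new[0]), np.array(p_new[1])):
            # small overshoots past the discrete boundary are projected
            # back inside; a gross exit flags inconsistent geometry/BCs
            cx, cy = geom.center
            rel = np.array([(p_new[0] - cx) / geom.a, (p_new[1] - cy) / geom.b])
            rho = float(np.hypot(*rel))
            if rho > 1.0 + step / min(geom.a, geom.b):
                raise RuntimeError(
                    f"streamline from {start} exited the spindle boundary at "
                    f"{p_new}; check geometry/boundary conditions"
                )
            rel *= 0.999 / rho
            p_new = np.array([cx + rel[0] * geom.a, cy + rel[1] * geom.b])
        # guard against stalls near the defect rim
        if np.hypot(*(p_new - pole_c)) > np.hypot(*(p - pole_c)) + step:
            p_new = p + step * (to_pole / np.linalg.norm(to_pole))
        pts.append(p_new)
        p = p_new
    else:
        raise RuntimeError(f"streamline from {start} did not reach pole {target_pole}")

    # entry point into the defect disk: final p (inside disk) — clip the
    # last chord exactly onto the disk edge for a clean s = r_defect there
    path = np.asarray(pts[::-1])  # ordered: near-pole ... start
    entry = path[0]
    r_entry = np.hypot(*(entry - pole_c))
    # radial prefix from pole center to the entry point
    radial_dir = (entry - pole_c) / max(r_entry, 1e-12)
    prefix = np.stack([pole_c, pole_c + radial_dir * min(r_entry, geom.defect_radius)])
    full = np.vstack([prefix, path]) if r_entry > 1e-9 else np.vstack([pole_c[None], path])
    seg = np.linalg.norm(np.diff(full, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    full = full[keep]
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(full, axis=0), axis=1))])
    return Streamline(points=full, s=s, pole=int(target_pole))


def seed_streamlines(
    field: DirectorField, spacing: float = 0.5, step: Optional[float] = None
) -> list[Streamline]:
    """Streamlines seeded on the equatorial midplane, one per seed per pole.

    Seeds sit on the line through the spindle center perpendicular to
    the axis, spaced ``spacing`` µm apart and symmetric about the axis;
    each seed is traced to both poles and the two halves returned as
    separate streamlines.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    geom = field.geometry
    cx, cy = geom.center
    half_width = geom.b
    n_side = int(np.floor(half_width / spacing + 1e-9))
    offsets = np.arange(-n_side, n_side + 1) * spacing
    if field.axisymmetric:
        offsets = offsets[offsets >= 0]
    lines: list[Streamline] = []
    margin = field.spacing / 2
    for off in offsets:
        seed = np.array([cx, cy + off])
        # nudge edge seeds inside by half a grid cell so the traced
        # streamline does not hug the discrete boundary
        if abs(off) > half_width - margin:
            seed[1] = cy + np.sign(off) * (half_width - margin)
        for pole in (0, 1):
            lines.append(trace_streamline(field, seed, pole, step=step))
    return lines


def streamline_position(
    field: DirectorField, point: np.ndarray, pole: Optional[int] = None, step: Optional[float] = None
) -> float:
    """Arc-length coordinate s of ``point``: distance to the pole along
    the streamline through the point.  If ``pole`` is None the nearer
    defect is used."""
    point = np.asarray(point, dtype=float)
    if pole is None:
        d = np.linalg.norm(field.geometry.defect_centers - point[None, :], axis=1)
        pole = int(np.argmin(d))
    sl = trace_streamline(field, point, pole, step=step)
    return sl.s_max
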