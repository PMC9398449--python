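"""Domain types, readers/writers and validation for spindle data.

Canonical conventions used throughout the package:

* All coordinates are in micrometres (µm), right-handed.
* The spindle axis is the line through the two poles (mother-centriole
  centers); per-half-spindle analyses assign each KMT to the pole on its
  kinetochore's side of the equatorial plane.
* All distance cutoffs are closed thresholds (``<=``).
* Microtubule polylines store an ordered vertex list; the plus end is
  the kinetochore-embedded terminus of a KMT, the minus end the
  pole-facing terminus.

Exchange formats are plain text: a columnar vertex table (CSV) plus a
JSON sidecar for poles/kinetochores/metadata; movies are multi-page TIFF
with delimited-text pole tracks; orientation maps are paired
angle/weight arrays in delimited text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

KMT = "KMT"
NON_KMT = "non-KMT"

#: Default pole-proximity threshold (µm) used when reporting the
#: fraction of KMT minus ends "near" a pole.
POLE_DISTANCE_THRESHOLD_UM = 1.7


class SchemaError(ValueError):
    """A file or record violates the documented schema."""


@dataclass(frozen=True)
class MicrotubulePolyline:
    """A single microtubule traced as an ordered 3D polyline (µm).

    ``plus_end``/``minus_end`` are vertex indices of the two termini
    (0 or ``len(points) - 1``).  ``cls`` is ``"KMT"`` or ``"non-KMT"``;
    KMTs carry the id of the kinetochore their plus end is embedded in.
    """

    points: np.ndarray
    plus_end: int
    minus_end: int
    cls: str = NON_KMT
    kinetochore_id: Optional[int] = None
    mt_id: Optional[int] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise SchemaError(
                f"MT {self.mt_id}: polyline must be an (n>=2, 3) array, got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise SchemaError(f"MT {self.mt_id}: non-finite coordinates")
        n = pts.shape[0]
        ends = {self.plus_end, self.minus_end}
        if ends != {0, n - 1}:
            raise SchemaError(
                f"MT {self.mt_id}: plus/minus ends must be the two termini "
                f"(0 and {n - 1}), got {self.plus_end}, {self.minus_end}"
            )
        if self.arc_length() <= 0:
            raise SchemaError(f"MT {self.mt_id}: zero arc length")
        if self.cls not in (KMT, NON_KMT):
            raise SchemaError(f"MT {self.mt_id}: unknown class {self.cls!r}")
        if (self.cls == KMT) != (self.kinetochore_id is not None):
            raise SchemaError(
                f"MT {self.mt_id}: KMT label and kinetochore_id must come together"
            )

    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def plus_point(self) -> np.ndarray:
        return self.points[self.plus_end]

    @property
    def minus_point(self) -> np.ndarray:
        return self.points[self.minus_end]


@dataclass(frozen=True)
class SpindleReconstruction:
    """A reconstructed spindle: microtubules, two poles, kinetochores."""

    mts: tuple[MicrotubulePolyline, ...]
    poles: np.ndarray  # (2, 3) µm, mother-centriole centers
    kinetochores: tuple[tuple[int, np.ndarray], ...]  # (id, 3D point)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        poles = np.asarray(self.poles, dtype=float)
        object.__setattr__(self, "poles", poles)
        if poles.shape != (2, 3):
            raise SchemaError(f"exactly two 3D poles required, got shape {poles.shape}")
        if not np.all(np.isfinite(poles)):
            raise SchemaError("non-finite pole coordinates")
        kts = tuple((int(k), np.asarray(p, dtype=float)) for k, p in self.kinetochores)
        object.__setattr__(self, "kinetochores", kts)
        kt_ids = {k for k, _ in kts}
        if len(kt_ids) != len(kts):
            raise SchemaError("duplicate kinetochore ids")
        for p in (p for _, p in kts):
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise SchemaError("kinetochore points must be finite 3-vectors")
        object.__setattr__(self, "mts", tuple(self.mts))
        for mt in self.mts:
            if mt.cls == KMT and mt.kinetochore_id not in kt_ids:
                raise SchemaError(
                    f"MT {mt.mt_id}: references unknown kinetochore {mt.kinetochore_id}"
                )

    @property
    def kmts(self) -> tuple[MicrotubulePolyline, ...]:
        return tuple(mt for mt in self.mts if mt.cls == KMT)

    @property
    def non_kmts(self) -> tuple[MicrotubulePolyline, ...]:
        return tuple(mt for mt in self.mts if mt.cls == NON_KMT)

    def kinetochore_point(self, kt_id: int) -> np.ndarray:
        for k, p in self.kinetochores:
            if k == kt_id:
                return p
        raise KeyError(kt_id)

    @property
    def spindle_axis(self) -> np.ndarray:
        """Unit vector from pole 0 to pole 1."""
        d = self.poles[1] - self.poles[0]
        return d / np.linalg.norm(d)

    def nearer_pole(self, point: np.ndarray) -> int:
        d = np.linalg.norm(self.poles - np.asarray(point)[None, :], axis=1)
        return int(np.argmin(d))


@dataclass(frozen=True)
class PhotoconversionMovie:
    """Time-lapse of a photoconversion experiment.

    ``frames``: (T, H, W) intensity; ``pole_tracks``: (T, 2, 2) array of
    per-frame 2D pole-marker positions in pixel coordinates (x, y);
    ``activation_line``: 2D segment ((x0, y0), (x1, y1)) in pixels.
    """

    frames: np.ndarray
    pixel_size: float  # µm / px
    frame_interval: float  # s
    pole_tracks: np.ndarray
    activation_frame: int = 0
    activation_line: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        tracks = np.asarray(self.pole_tracks, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "pole_tracks", tracks)
        if frames.ndim != 3:
            raise SchemaError("frames must be a (T, H, W) stack")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise SchemaError("pixel_size and frame_interval must be positive")
        if tracks.shape != (frames.shape[0], 2, 2):
            raise SchemaError(
                f"pole_tracks must have shape (T, 2, 2)={(frames.shape[0], 2, 2)}, "
                f"got {tracks.shape}"
            )
        if not np.all(np.isfinite(tracks)):
            raise SchemaError("pole tracks must be finite for all analysed frames")
        if self.activation_line is not None:
            line = np.asarray(self.activation_line, dtype=float)
            object.__setattr__(self, "activation_line", line)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_min(self) -> np.ndarray:
        """Time of each frame in minutes, zero at the activation frame."""
        t = (np.arange(self.n_frames) - self.activation_frame) * self.frame_interval
        return t / 60.0


@dataclass(frozen=True)
class OrientationMap:
    """PolScope-like 2D map of mean orientation and weight.

    ``angle`` is interpreted modulo π (nematic, headless); ``weight`` is
    a non-negative density proxy (retardance).  The grid spans the
    spindle-axis × radial-axis plane with square bins of ``bin_size`` µm;
    ``origin`` is the (axis, radial) coordinate of the cell (0, 0) center.
    """

    angle: np.ndarray
    weight: np.ndarray
    bin_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        a = np.asarray(self.angle, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        if a.shape != w.shape or a.ndim != 2:
            raise SchemaError("angle and weight must be equal-shape 2D arrays")
        if np.any(w < 0):
            raise SchemaError("weights must be >= 0")
        # canonicalize angles into (-pi/2, pi/2]
        a = np.mod(a + np.pi / 2, np.pi) - np.pi / 2
        object.__setattr__(self, "angle", a)
        object.__setattr__(self, "weight", w)
        if self.bin_size <= 0:
            raise SchemaError("bin_size must be positive")


# ---------------------------------------------------------------------------
# reconstruction table I/O


_VERTEX_COLUMNS = ["mt_id", "vertex", "x_um", "y_um", "z_um"]
_MT_COLUMNS = ["mt_id", "cls", "plus_end", "minus_end", "kinetochore_id"]


def save_reconstruction(rec: SpindleReconstruction, path: str | Path) -> None:
    """Write a reconstruction as ``<path>.csv`` + ``<path>.json`` sidecar.

    Floats are written with ``repr`` round-trip precision so that
    save→load reproduces coordinates bit-exactly.
    """
    path = Path(path)
    rows = []
    mt_rows = []
    for i, mt in enumerate(rec.mts):
        mt_id = mt.mt_id if mt.mt_id is not None else i
        for j, p in enumerate(mt.points):
            rows.append((mt_id, j, p[0], p[1], p[2]))
        mt_rows.append(
            {
                "mt_id": mt_id,
                "cls": mt.cls,
                "plus_end": mt.plus_end,
                "minus_end": mt.minus_end,
                "kinetochore_id": mt.kinetochore_id,
            }
        )
    df = pd.DataFrame(rows, columns=_VERTEX_COLUMNS)
    df.to_csv(path.with_suffix(".csv"), index=False, float_format=None)
    sidecar = {
        "poles": [[float(x) for x in p] for p in rec.poles],
        "kinetochores": [
            {"id": int(k), "point": [float(x) for x in p]} for k, p in rec.kinetochores
        ],
        "mts": mt_rows,
        "meta": dict(rec.meta),
        "units": "um",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_reconstruction(path: str | Path) -> SpindleReconstruction:
    """Load a reconstruction from the package's columnar text format.

    ``path`` may point at either the ``.csv`` vertex table or the
    ``.json`` sidecar; both must exist.  Raises :class:`SchemaError`
    naming the offending record on any contract violation.
    """
    path = Path(path)
    csv_path, json_path = path.with_suffix(".csv"), path.with_suffix(".json")
    if not csv_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"need both {csv_path} and {json_path}")
    df = pd.read_csv(csv_path)
    missing = [c for c in _VERTEX_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{csv_path}: missing columns {missing}")
    sidecar = json.loads(json_path.read_text())
    mt_info = {int(m["mt_id"]): m for m in sidecar["mts"]}
    mts = []
    for mt_id, grp in df.groupby("mt_id", sort=True):
        info = mt_info.get(int(mt_id))
        if info is None:
            raise SchemaError(f"mt_id {mt_id} present in table but not in sidecar")
        grp = grp.sort_values("vertex")
        pts = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(pts)):
            raise SchemaError(f"MT {mt_id}: non-finite coordinates in {csv_path}")
        kt = info.get("kinetochore_id")
        mts.append(
            MicrotubulePolyline(
                points=pts,
                plus_end=int(info["plus_end"]),
                minus_end=int(info["minus_end"]),
                cls=str(info["cls"]),
                kinetochore_id=None if kt is None else int(kt),
                mt_id=int(mt_id),
            )
        )
    rec = SpindleReconstruction(
        mts=tuple(mts),
        poles=np.asarray(sidecar["poles"], dtype=float),
        kinetochores=tuple(
            (int(k["id"]), np.asarray(k["point"], dtype=float))
            for k in sidecar["kinetochores"]
        ),
        meta=sidecar.get("meta", {}),
    )
    return rec


# ---------------------------------------------------------------------------
# KMT classification and minus-end statistics


def classify_kmts(rec: SpindleReconstruction, attach_radius: float) -> SpindleReconstruction:
    """Label MTs with a terminus within ``attach_radius`` of a kinetochore as KMTs.

    The terminus nearest a kinetochore becomes the plus end (ties broken
    by the nearest kinetochore; the threshold is closed, ``<=``).  MTs
    with no terminus within reach are labelled non-KMT.  Idempotent.
    With no kinetochores, every MT becomes non-KMT.
    """
    if attach_radius <= 0:
        raise ValueError("attach_radius must be > 0")
    kt_ids = np.array([k for k, _ in rec.kinetochores], dtype=int)
    kt_pts = (
        np.array([p for _, p in rec.kinetochores], dtype=float)
        if rec.kinetochores
        else np.zeros((0, 3))
    )
    new_mts = []
    for mt in rec.mts:
        termini = np.stack([mt.points[0], mt.points[-1]])  # (2, 3)
        if len(kt_pts) == 0:
            new_mts.append(
                replace(mt, cls=NON_KMT, kinetochore_id=None)
            )
            continue
        d = np.linalg.norm(termini[:, None, :] - kt_pts[None, :, :], axis=2)  # (2, K)
        flat = int(np.argmin(d))
        ti, ki = divmod(flat, d.shape[1])
        if d[ti, ki] <= attach_radius:
            plus = 0 if ti == 0 else len(mt.points) - 1
            minus = len(mt.points) - 1 - plus
            new_mts.append(
                replace(
                    mt,
                    cls=KMT,
                    kinetochore_id=int(kt_ids[ki]),
                    plus_end=plus,
                    minus_end=minus,
                )
            )
        else:
            new_mts.append(replace(mt, cls=NON_KMT, kinetochore_id=None))
    return replace(rec, mts=tuple(new_mts))


def minus_end_pole_distances(
    rec: SpindleReconstruction, threshold: float = POLE_DISTANCE_THRESHOLD_UM
) -> pd.DataFrame:
    """3D distance from each KMT minus end to its half-spindle's pole.

    The KMT is assigned to the pole nearer its kinetochore.  Returns a
    DataFrame with columns ``mt_id, pole, distance_um, within`` where
    ``within`` marks distances ``<= threshold`` (closed interval).  The
    overall near-pole fraction is stored in ``df.attrs["fraction_within"]``.
    """
    kmts = rec.kmts
    if not kmts:
        raise ValueError("reconstruction contains no KMTs")
    rows = []
    for i, mt in enumerate(kmts):
        kt_point = rec.kinetochore_point(mt.kinetochore_id)
        pole_id = rec.nearer_pole(kt_point)
        d = float(np.linalg.norm(mt.minus_point - rec.poles[pole_id]))
        rows.append(
            {
                "mt_id": mt.mt_id if mt.mt_id is not None else i,
                "pole": pole_id,
                "distance_um": d,
                "within": d <= threshold,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["threshold_um"] = float(threshold)
    df.attrs["fraction_within"] = float(df["within"].mean())
    return df


# ---------------------------------------------------------------------------
# movie I/O


def save_movie(movie: PhotoconversionMovie, path: str | Path) -> None:
    """Write frames as multi-page TIFF plus ``<path>.poles.tsv`` and JSON meta."""
    path = Path(path)
    tifffile.imwrite(
        path.with_suffix(".tif"),
        movie.frames.astype(np.float32),
        photometric="minisblack",
    )
    t = np.arange(movie.n_frames)
    tracks = movie.pole_tracks
    df = pd.DataFrame(
        {
            "frame": t,
            "pole0_x": tracks[:, 0, 0],
            "pole0_y": tracks[:, 0, 1],
            "pole1_x": tracks[:, 1, 0],
            "pole1_y": tracks[:, 1, 1],
        }
    )
    df.to_csv(path.with_suffix(".poles.tsv"), sep="\t", index=False)
    meta = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "activation_frame": movie.activation_frame,
        "activation_line": None
        if movie.activation_line is None
        else np.asarray(movie.activation_line).tolist(),
        "meta": dict(movie.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_movie(path: str | Path) -> PhotoconversionMovie:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path.with_suffix(".tif")), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    df = pd.read_csv(path.with_suffix(".poles.tsv"), sep="\t")
    tracks = np.stack(
        [
            df[["pole0_x", "pole0_y"]].to_numpy(),
            df[["pole1_x", "pole1_y"]].to_numpy(),
        ],
        axis=1,
    )
    meta = json.loads(path.with_suffix(".json").read_text())
    line = meta.get("activation_line")
    return PhotoconversionMovie(
        frames=frames,
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_s"]),
        pole_tracks=tracks,
        activation_frame=int(meta.get("activation_frame", 0)),
        activation_line=None if line is None else np.asarray(line, dtype=float),
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# orientation map I/O


def save_orientation_map(omap: OrientationMap, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path.with_suffix(".angle.tsv"), omap.angle, delimiter="\t")
    np.savetxt(path.with_suffix(".weight.tsv"), omap.weight, delimiter="\t")
    meta = {"bin_size_um": omap.bin_size, "origin": list(omap.origin)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_orientation_map(path: str | Path) -> OrientationMap:
    path = Path(path)
    angle = np.atleast_2d(np.loadtxt(path.with_suffix(".angle.tsv"), delimiter="\t"))
    weight = np.atleast_2d(np.loadtxt(path.with_suffix(".weight.tsv"), delimiter="\t"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return OrientationMap(
        angle=angle,
        weight=weight,
        bin_size=float(meta["bin_size_um"]),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )


def validate(path: str | Path) -> str:
    """Validate a data file bundle by extension; returns the detected kind."""
    path = Path(path)
    if path.with_suffix(".csv").exists() and path.with_suffix(".json").exists():
        load_reconstruction(path)
        return "reconstruction"
    if path.with_suffix(".tif").exists():
        load_movie(path)
        return "movie"
    if path.with_suffix(".angle.tsv").exists():
        load_orientation_map(path)
        return "orientation_map"
    raise FileNotFoundError(f"no recognized data bundle at {path}")


# ---------------------------------------------------------------------------
# spindle frame helpers (shared coordinate convention)


def spindle_frame(poles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (origin, rotation) mapping lab µm coords to the spindle frame.

    The frame origin is the midpoint between the poles; the x axis points
    from pole 0 to pole 1; y and z complete a right-handed basis with y
    chosen in the lab-z-least direction for reproducibility.
    """
    poles = np.asarray(poles, dtype=float)
    origin = poles.mean(axis=0)
    ex = poles[1] - poles[0]
    ex = ex / np.linalg.norm(ex)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ex, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    R = np.stack([ex, ey, ez])  # rows are basis vectors
    return origin, R


def to_spindle_frame(points: np.ndarray, poles: np.ndarray) -> np.ndarray:
    """Transform (n, 3) lab-frame points into the spindle frame."""
    origin, R = spindle_frame(poles)
    return (np.asarray(points, dtype=float) - origin) @ R.T
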