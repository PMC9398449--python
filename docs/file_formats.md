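# File formats

All exchange formats are plain text (plus multi-page TIFF for movie
frames). Coordinates are micrometres, right-handed; the spindle axis is
the line through the two poles. Floats round-trip exactly.

## Spindle reconstruction: `<name>.csv` + `<name>.json`

Vertex table (`.csv`), one row per polyline vertex:

| column | meaning |
|---|---|
| `mt_id` | integer microtubule id (groups vertices) |
| `vertex` | vertex index along the polyline, 0-based |
| `x_um`, `y_um`, `z_um` | 3D position in µm |

Sidecar (`.json`):

```json
{
 "poles": [[x, y, z], [x, y, z]],
 "kinetochores": [{"id": 7, "point": [x, y, z]}, ...],
 "mts": [{"mt_id": 0, "cls": "KMT", "plus_end": 0, "minus_end": 12,
          "kinetochore_id": 7}, ...],
 "meta": {},
 "units": "um"
}
```

`cls` is `"KMT"` or `"non-KMT"`; a KMT must carry a `kinetochore_id`
referencing an entry of `kinetochores`, and `plus_end`/`minus_end` are the
vertex indices of the two termini. Validation rejects non-finite
coordinates, polylines with fewer than two points or zero arc length, and
dangling kinetochore references, naming the offending record.

## Photoconversion movie: `<name>.tif` + `<name>.poles.tsv` + `<name>.json`

* `.tif` — one page per frame, float32 intensity.
* `.poles.tsv` — columns `frame, pole0_x, pole0_y, pole1_x, pole1_y`
  (pixel coordinates, one row per frame).
* `.json` — `pixel_size_um`, `frame_interval_s`, `activation_frame`,
  optional `activation_line` (2D pixel segment), free-form `meta`.

## Orientation map: `<name>.angle.tsv` + `<name>.weight.tsv` + `<name>.json`

Two equal-shape tab-delimited 2D arrays — mean orientation angle in
radians (interpreted modulo π) and a non-negative weight (retardance /
density proxy) — plus a JSON with `bin_size_um` and the `origin`
coordinate of cell (0, 0).

## Ancillary tables

* Minus-end tables (`kfibers flux solve` input): CSV with `minus_s`,
  `plus_s` — per-KMT streamline arc-length coordinates in µm.
* Speed datasets (`kfibers compare run` input): CSV with `position_um`,
  `speed_um_per_min`, `sem`.
* Geometry YAML (`kfibers field solve`): keys `a`, `b`, `defect_x`
  (two-element list), `defect_radius`, optional `center`.
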