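"""Readers and writers for the three supported landmark dialects.

* Bosphorus-style text files: a comment header, a point count, then
  alternating name / ``x y z`` lines.  Landmark names are mapped onto
  the canonical 22-point scheme through an editable table shipped with
  the package (the two ear-lobe points of 24-point files are dropped).
* A generic long-form CSV (columns ``subject_id, expression,
  landmark_index, x, y, z``) and an equivalent JSON document; both
  round-trip losslessly and are what the synthetic generator emits.
* 51-point avatar landmark lists, adapted to the 22-point scheme by a
  versioned mapping table: 19 points are copied directly and three
  (the two nose saddles and the outer middle of the upper lip) are
  synthesized as midpoints of two named donor points each.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .landmarks import CANONICAL_NAMES, Expression, Landmark, LandmarkSet, N_LANDMARKS

__all__ = [
    "RawUibvfedSet",
    "UIBVFED_SCHEME",
    "read_bosphorus_landmarks",
    "write_bosphorus_landmarks",
    "adapt_uibvfed",
    "read_generic",
    "write_generic",
    "read_generic_json",
    "write_generic_json",
]


def _data_path(name: str):
    return resources.files("geomexpr.data").joinpath(name)


def _load_bosphorus_name_table() -> Dict[str, int]:
    """Landmark-file name -> canonical index (0 = ignored point)."""
    table: Dict[str, int] = {}
    with _data_path("bosphorus_names.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[row["file_name"].strip().lower()] = int(row["canonical_index"])
    return table


#: The 51 named points of the avatar (UIBVFED-style) annotation scheme,
#: in their file order: eyebrows (10), eyes (12), nose (9), outer lip
#: (9), inner lip (8), chin (3).
UIBVFED_SCHEME: Tuple[str, ...] = (
    "left eyebrow outer", "left eyebrow mid outer", "left eyebrow mid",
    "left eyebrow mid inner", "left eyebrow inner",
    "right eyebrow inner", "right eyebrow mid inner", "right eyebrow mid",
    "right eyebrow mid outer", "right eyebrow outer",
    "left eye outer corner", "left eye upper outer", "left eye upper inner",
    "left eye inner corner", "left eye lower inner", "left eye lower outer",
    "right eye inner corner", "right eye upper inner", "right eye upper outer",
    "right eye outer corner", "right eye lower outer", "right eye lower inner",
    "nasion", "nose bridge upper", "nose bridge lower", "nose tip",
    "nose wing left", "nostril left", "subnasale", "nostril right", "nose wing right",
    "mouth corner left", "outer lip upper left", "upper lip peak left",
    "upper lip peak right", "outer lip upper right", "mouth corner right",
    "outer lip lower right", "outer lip lower middle", "outer lip lower left",
    "inner mouth corner left", "inner lip upper left", "inner lip upper middle",
    "inner lip upper right", "inner mouth corner right", "inner lip lower right",
    "inner lip lower middle", "inner lip lower left",
    "chin left", "chin middle", "chin right",
)


@dataclass
class RawUibvfedSet:
    """One avatar face in the 51-point scheme, prior to adaptation."""

    subject_id: str
    expression: Expression
    points: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.points) != 51:
            raise ValueError(f"expected 51 points, got {len(self.points)}")
        missing = set(UIBVFED_SCHEME) - set(self.points)
        if missing:
            raise ValueError(f"51-point set missing: {sorted(missing)}")


def read_bosphorus_landmarks(
    path, subject_id: str | None = None, expression: Expression = Expression.NEUTRAL
) -> LandmarkSet:
    """Parse a Bosphorus-style landmark text file into a LandmarkSet.

    Structure: optional ``#`` comment lines, one line with the number
    of points, then for each point a name line followed by a
    whitespace-separated ``x y z`` line.  Points whose name is not in
    the canonical table (e.g. ear lobes) are ignored; a missing
    canonical point is an error naming it.
    """
    path = Path(path)
    name_table = _load_bosphorus_name_table()
    lines = path.read_text().splitlines()
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.lstrip().startswith("#")]
    if not body:
        raise ValueError(f"{path}: empty landmark file")
    lineno, count_line = body[0]
    try:
        n_points = int(count_line.split()[0])
    except ValueError:
        raise ValueError(f"{path}:{lineno}: expected a point count, got {count_line!r}") from None
    records = body[1:]
    if len(records) < 2 * n_points:
        raise ValueError(f"{path}: header announces {n_points} points but only "
                         f"{len(records) // 2} records follow")
    points: Dict[int, Landmark] = {}
    for k in range(n_points):
        _, name_line = records[2 * k]
        lineno, coord_line = records[2 * k + 1]
        parts = coord_line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: malformed coordinate line {coord_line!r}")
        try:
            x, y, z = (float(p) for p in parts)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed coordinate line {coord_line!r}") from None
        idx = name_table.get(name_line.strip().lower())
        if idx is None:
            warnings.warn(f"{path}: unknown landmark name {name_line.strip()!r}; ignored")
            continue
        if idx == 0:  # explicitly excluded point (ear region)
            continue
        points[idx] = Landmark(idx, CANONICAL_NAMES[idx], x, y, z)
    missing = sorted(set(CANONICAL_NAMES) - set(points))
    if missing:
        names = ", ".join(CANONICAL_NAMES[i] for i in missing)
        raise ValueError(f"{path}: canonical landmark(s) absent: {names}")
    return LandmarkSet(
        subject_id=subject_id if subject_id is not None else path.stem,
        expression=expression,
        points=points,
    )


def write_bosphorus_landmarks(ls: LandmarkSet, path) -> None:
    """Write a LandmarkSet in the Bosphorus-style text dialect."""
    out = ["# Landmark file", f"{N_LANDMARKS}"]
    for i in range(1, N_LANDMARKS + 1):
        p = ls.points[i]
        out.append(p.name)
        out.append(f"{p.x!r} {p.y!r} {p.z!r}")
    Path(path).write_text("\n".join(out) + "\n")


def _load_uibvfed_mapping() -> List[dict]:
    rows = []
    with _data_path("uibvfed_mapping.csv").open() as fh:
        reader = csv.DictReader(ln for ln in fh if not ln.startswith("#"))
        for row in reader:
            rows.append(
                {
                    "canonical_index": int(row["canonical_index"]),
                    "source": row["source"].strip() or None,
                    "donors": (row["donor_a"].strip(), row["donor_b"].strip())
                    if row["donor_a"].strip()
                    else None,
                }
            )
    return rows


def adapt_uibvfed(raw: RawUibvfedSet) -> LandmarkSet:
    """Convert a 51-point avatar face to the canonical 22-point scheme.

    Because every target point is either a copy or a midpoint, the
    adaptation commutes with any global similarity transform applied
    to the raw points.
    """
    points: Dict[int, Landmark] = {}
    for row in _load_uibvfed_mapping():
        idx = row["canonical_index"]
        if row["source"] is not None:
            xyz = np.asarray(raw.points[row["source"]], dtype=float)
        else:
            a_name, b_name = row["donors"]
            a = np.asarray(raw.points[a_name], dtype=float)
            b = np.asarray(raw.points[b_name], dtype=float)
            if np.allclose(a, b):
                warnings.warn(
                    f"coincident donor points {a_name!r}/{b_name!r} while "
                    f"interpolating canonical landmark {idx}"
                )
            xyz = 0.5 * (a + b)
        points[idx] = Landmark(idx, CANONICAL_NAMES[idx], *xyz)
    return LandmarkSet(subject_id=raw.subject_id, expression=raw.expression, points=points)


_GENERIC_COLUMNS = ["subject_id", "expression", "landmark_index", "x", "y", "z"]


def write_generic(sets: Sequence[LandmarkSet], path) -> None:
    """Write landmark sets as long-form CSV (lossless round-trip)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_GENERIC_COLUMNS)
        for ls in sets:
            for i in range(1, N_LANDMARKS + 1):
                p = ls.points[i]
                w.writerow([ls.subject_id, ls.expression.value, i, repr(p.x), repr(p.y), repr(p.z)])


def read_generic(path) -> List[LandmarkSet]:
    """Read the long-form CSV written by :func:`write_generic`."""
    df = pd.read_csv(
        path, dtype={"subject_id": str, "expression": str}, float_precision="round_trip"
    )
    missing_cols = set(_GENERIC_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    dup = df.duplicated(subset=["subject_id", "expression", "landmark_index"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate row for subject {first['subject_id']!r} "
            f"landmark {int(first['landmark_index'])}"
        )
    sets: List[LandmarkSet] = []
    keys = df[["subject_id", "expression"]].drop_duplicates(keep="first")
    grouped = df.groupby(["subject_id", "expression"], sort=False)
    for key in keys.itertuples(index=False):
        g = grouped.get_group((key.subject_id, key.expression))
        pts = {
            int(r.landmark_index): Landmark(
                int(r.landmark_index), CANONICAL_NAMES[int(r.landmark_index)], r.x, r.y, r.z
            )
            for r in g.itertuples(index=False)
        }
        sets.append(
            LandmarkSet(
                subject_id=key.subject_id,
                expression=Expression.from_code(key.expression),
                points=pts,
            )
        )
    return sets


def write_generic_json(sets: Sequence[LandmarkSet], path) -> None:
    """JSON twin of :func:`write_generic`."""
    doc = {
        "format": "geomexpr-landmarks",
        "version": 1,
        "sets": [
            {
                "subject_id": ls.subject_id,
                "expression": ls.expression.value,
                "landmarks": [
                    {"index": i, "x": ls.points[i].x, "y": ls.points[i].y, "z": ls.points[i].z}
                    for i in range(1, N_LANDMARKS + 1)
                ],
            }
            for ls in sets
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_generic_json(path) -> List[LandmarkSet]:
    doc = json.loads(Path(path).read_text())
    sets = []
    for rec in doc["sets"]:
        seen = set()
        pts = {}
        for lm in rec["landmarks"]:
            i = int(lm["index"])
            if i in seen:
                raise ValueError(
                    f"{path}: duplicate landmark {i} for subject {rec['subject_id']!r}"
                )
            seen.add(i)
            pts[i] = Landmark(i, CANONICAL_NAMES[i], lm["x"], lm["y"], lm["z"])
        sets.append(
            LandmarkSet(
                subject_id=rec["subject_id"],
                expression=Expression.from_code(rec["expression"]),
                points=pts,
            )
        )
    return sets
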