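"""Geometric feature extraction from landmark sets.

Distances are Euclidean norms, d(p1, p2) = ||p1 - p2||, divided by the
inner-eye-corner separation (landmarks 8-9, measured in 3D) so that
they are scale-free.  Angles are computed at the vertex p2 of a triple
(p1, p2, p3) as

    A = arccos( (p3 - p2) . (p1 - p2) / (||p3 - p2|| ||p1 - p2||) )

in radians; they are intrinsically scale-free and therefore not
normalized.  2D variants use the X-Y projection of the landmarks
(frontal-pose assumption: the projection simply drops Z).

All 3D features are invariant under global similarity transforms of
the face (rotation + translation + uniform scaling); 2D features are
invariant only under in-plane similarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, builtin_catalog
from .landmarks import Expression, LandmarkSet

__all__ = [
    "euclidean_distance",
    "angle",
    "normalizer",
    "extract_features",
    "FeatureVector",
    "FeatureMatrix",
    "extract_matrix",
]


def euclidean_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean norm of p - q (works for 2D and 3D points)."""
    return float(np.linalg.norm(np.asarray(p, dtype=float) - np.asarray(q, dtype=float)))


def angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle in radians at vertex ``p2`` of the triple (p1, p2, p3).

    The cosine is clamped to [-1, 1] before the arccos so that
    floating-point round-off on (anti)parallel arms can never produce
    a NaN.  A zero-length arm is an error identifying the degenerate
    pair.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0:
        raise ValueError("degenerate angle: p1 coincides with vertex p2")
    if nv == 0.0:
        raise ValueError("degenerate angle: p3 coincides with vertex p2")
    cosine = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosine))


def normalizer(ls: LandmarkSet) -> float:
    """3D distance between canonical landmarks 8 and 9.

    This single value normalizes every distance feature (2D and 3D
    alike), making the feature vector unit-free.
    """
    d = euclidean_distance(ls[8].xyz, ls[9].xyz)
    if d <= 0.0:
        raise ValueError(f"zero landmark-8/9 distance for subject {ls.subject_id!r}")
    return d


@dataclass
class FeatureVector:
    """89 (or fewer, for a sub-catalog) feature values for one face."""

    values: np.ndarray
    ids: List[str]
    subject_id: str = ""
    expression: Expression = Expression.NEUTRAL

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.ids, name=self.subject_id)


def extract_features(ls: LandmarkSet, catalog: Optional[FeatureCatalog] = None) -> FeatureVector:
    """Compute the normalized geometric feature vector of one face."""
    if catalog is None:
        catalog = builtin_catalog()
    norm = normalizer(ls)
    values = np.empty(len(catalog))
    for j, desc in enumerate(catalog):
        pts = [ls[i].xyz if desc.space == "3D" else ls[i].xy for i in desc.landmarks]
        try:
            if desc.kind == "distance":
                values[j] = euclidean_distance(pts[0], pts[1]) / norm
            else:
                values[j] = angle(pts[0], pts[1], pts[2])
        except ValueError as exc:
            raise ValueError(f"feature {desc.id}: {exc}") from exc
    return FeatureVector(values=values, ids=catalog.ids,
                         subject_id=ls.subject_id, expression=ls.expression)


@dataclass
class FeatureMatrix:
    """n_faces x n_features values plus labels, aligned to a catalog."""

    X: np.ndarray
    y: np.ndarray  # expression codes, e.g. "SU"
    ids: List[str]
    subjects: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.ids):
            raise ValueError(
                f"feature matrix shape {self.X.shape} does not match {len(self.ids)} ids"
            )
        if len(self.y) != self.X.shape[0]:
            raise ValueError("label count does not match row count")
        if not self.subjects:
            self.subjects = [f"face_{i}" for i in range(self.X.shape[0])]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.ids)
        df.insert(0, "subject_id", self.subjects)
        df.insert(1, "expression", self.y)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, dtype={"subject_id": str, "expression": str})
        ids = [c for c in df.columns if c not in ("subject_id", "expression")]
        return cls(
            X=df[ids].to_numpy(dtype=float),
            y=df["expression"].to_numpy(),
            ids=ids,
            subjects=list(df["subject_id"]),
        )

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return FeatureMatrix(
            X=self.X[:, mask],
            y=self.y.copy(),
            ids=[i for i, keep in zip(self.ids, mask) if keep],
            subjects=list(self.subjects),
        )


def extract_matrix(
    sets: Sequence[LandmarkSet], catalog: Optional[FeatureCatalog] = None
) -> FeatureMatrix:
    """Extract features for a collection of faces into one matrix."""
    if catalog is None:
        catalog = builtin_catalog()
    rows = [extract_features(ls, catalog) for ls in sets]
    return FeatureMatrix(
        X=np.stack([r.values for r in rows]),
        y=np.array([r.expression.value for r in rows]),
        ids=catalog.ids,
        subjects=[r.subject_id for r in rows],
    )
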