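"""The 89-descriptor geometric feature catalog.

Each descriptor is either a normalized Euclidean distance between two
landmarks or an angle at the vertex of a three-landmark triple, in 3D
or on the frontal X-Y projection (2D).  The catalog is stored as a
data file rather than code so that a transcription error surfaces as
a test failure instead of silently redefining a feature.

Column/catalog order is fixed: 19 3D distances (1D3..19D3), 27 3D
angles (1A3..27A3), 23 2D distances (1D2..23D2), 20 2D angles
(1A2..20A2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import List, Tuple

import numpy as np

__all__ = [
    "FeatureDescriptor",
    "FeatureCatalog",
    "builtin_catalog",
    "ga_selected_ids",
    "ga_selected_mask",
    "ga_selected_catalog",
    "GROUP_ORDER",
]

#: Display order of descriptor groups in accounting reports.
GROUP_ORDER = ("3D_angle", "3D_distance", "2D_angle", "2D_distance")


@dataclass(frozen=True)
class FeatureDescriptor:
    """One geometric feature definition.

    ``landmarks`` holds canonical indices: two for a distance, three
    for an angle with the vertex as the middle element.
    """

    id: str
    kind: str  # "distance" | "angle"
    space: str  # "2D" | "3D"
    landmarks: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "angle"):
            raise ValueError(f"{self.id}: unknown kind {self.kind!r}")
        if self.space not in ("2D", "3D"):
            raise ValueError(f"{self.id}: unknown space {self.space!r}")
        expected = 2 if self.kind == "distance" else 3
        if len(self.landmarks) != expected:
            raise ValueError(
                f"{self.id}: {self.kind} needs {expected} landmarks, got {len(self.landmarks)}"
            )
        if not all(1 <= i <= 22 for i in self.landmarks):
            raise ValueError(f"{self.id}: landmark indices out of range: {self.landmarks}")

    @property
    def group(self) -> str:
        return f"{self.space}_{self.kind}"


class FeatureCatalog:
    """Ordered collection of feature descriptors.

    The full built-in catalog always has 89 entries with group counts
    (27 3D angles, 19 3D distances, 20 2D angles, 23 2D distances);
    masked sub-catalogs keep the same relative order.
    """

    def __init__(self, descriptors: List[FeatureDescriptor]):
        ids = [d.id for d in descriptors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate descriptor ids in catalog")
        self.descriptors = list(descriptors)

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, key):
        if isinstance(key, str):
            for d in self.descriptors:
                if d.id == key:
                    return d
            raise KeyError(key)
        return self.descriptors[key]

    @property
    def ids(self) -> List[str]:
        return [d.id for d in self.descriptors]

    def group_counts(self) -> dict:
        counts = {g: 0 for g in GROUP_ORDER}
        for d in self.descriptors:
            counts[d.group] += 1
        return counts

    def subset(self, mask: np.ndarray) -> "FeatureCatalog":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(self),):
            raise ValueError(f"mask length {mask.shape} does not match catalog length {len(self)}")
        return FeatureCatalog([d for d, keep in zip(self.descriptors, mask) if keep])

    def mask_for_ids(self, ids) -> np.ndarray:
        """Boolean mask over this catalog selecting the given ids."""
        wanted = set(ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise KeyError(f"ids not in catalog: {sorted(unknown)}")
        return np.array([d.id in wanted for d in self.descriptors], dtype=bool)


@lru_cache(maxsize=1)
def builtin_catalog() -> FeatureCatalog:
    """The full 89-descriptor catalog, loaded from the shipped table."""
    descriptors = []
    with resources.files("geomexpr.data").joinpath("feature_catalog.csv").open() as fh:
        for row in csv.DictReader(fh):
            lm = [int(row["p1"]), int(row["p2"])]
            if row["p3"].strip():
                lm.append(int(row["p3"]))
            descriptors.append(
                FeatureDescriptor(row["id"], row["kind"], row["space"], tuple(lm))
            )
    cat = FeatureCatalog(descriptors)
    if len(cat) != 89:
        raise RuntimeError(f"catalog data file has {len(cat)} entries, expected 89")
    return cat


@lru_cache(maxsize=1)
def ga_selected_ids() -> Tuple[str, ...]:
    """Ids of the 47 descriptors retained by the best GA fit."""
    with resources.files("geomexpr.data").joinpath("ga_selected_ids.txt").open() as fh:
        ids = tuple(ln.strip() for ln in fh if ln.strip() and not ln.startswith("#"))
    return ids


def ga_selected_mask() -> np.ndarray:
    """47-feature selection as a boolean mask over the built-in catalog."""
    return builtin_catalog().mask_for_ids(ga_selected_ids())


def ga_selected_catalog() -> FeatureCatalog:
    """The 47 GA-selected descriptors as a sub-catalog."""
    return builtin_catalog().subset(ga_selected_mask())
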