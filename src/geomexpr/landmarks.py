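"""Canonical 22-point facial landmark scheme and its container types.

The scheme covers the eyebrow, eye, nose, mouth and chin regions of a
frontal face.  Coordinates are right-handed: X rightward (subject's
left is at negative X in image convention used here), Y upward, Z
toward the camera.  Units are millimetres for real capture data, but
nothing downstream depends on the unit because every distance feature
is normalized by the inner-eye-corner separation (landmarks 8-9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Mapping

import numpy as np

__all__ = [
    "Expression",
    "Landmark",
    "LandmarkSet",
    "CANONICAL_NAMES",
    "N_LANDMARKS",
    "MIRROR_PAIRS",
    "MIDLINE_POINTS",
]

N_LANDMARKS = 22

#: Canonical index -> anatomical name.  Indices 1-22 follow the usual
#: eyebrow / eye / nose / mouth / chin reading order of 3D face
#: databases with manually annotated landmarks ("left" = subject's left
#: as seen in the image, i.e. negative X).
CANONICAL_NAMES: Dict[int, str] = {
    1: "Outer left eyebrow",
    2: "Middle left eyebrow",
    3: "Inner left eyebrow",
    4: "Inner right eyebrow",
    5: "Middle right eyebrow",
    6: "Outer right eyebrow",
    7: "Outer left eye corner",
    8: "Inner left eye corner",
    9: "Inner right eye corner",
    10: "Outer right eye corner",
    11: "Nose saddle left",
    12: "Nose saddle right",
    13: "Left nose peak",
    14: "Nose tip",
    15: "Right nose peak",
    16: "Left mouth corner",
    17: "Upper lip outer middle",
    18: "Right mouth corner",
    19: "Upper lip inner middle",
    20: "Lower lip inner middle",
    21: "Lower lip outer middle",
    22: "Chin middle",
}

#: Bilaterally mirrored index pairs (left, right); used by the
#: synthetic generator to keep displacement tables symmetric.
MIRROR_PAIRS = ((1, 6), (2, 5), (3, 4), (7, 10), (8, 9), (11, 12), (13, 15), (16, 18))

#: Indices lying on the midsagittal plane (x == 0 on a symmetric face).
MIDLINE_POINTS = (14, 17, 19, 20, 21, 22)


class Expression(str, Enum):
    """The six basic facial expressions plus the neutral state."""

    ANGER = "AN"
    DISGUST = "DI"
    FEAR = "FE"
    HAPPINESS = "HA"
    SADNESS = "SA"
    SURPRISE = "SU"
    NEUTRAL = "NE"

    @classmethod
    def from_code(cls, code: str) -> "Expression":
        try:
            return cls(code.upper())
        except ValueError:
            raise ValueError(
                f"unknown expression code {code!r}; expected one of "
                f"{[e.value for e in cls]}"
            ) from None


#: Fixed display order used in every report and confusion matrix.
DISPLAY_ORDER = ("SU", "SA", "HA", "FE", "DI", "AN")


@dataclass(frozen=True)
class Landmark:
    """A single named anatomical point."""

    index: int
    name: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_LANDMARKS:
            raise ValueError(f"landmark index {self.index} outside [1, {N_LANDMARKS}]")
        for attr in ("x", "y", "z"):  # plain floats: keeps repr()-based writers lossless
            object.__setattr__(self, attr, float(getattr(self, attr)))
        if not all(np.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for landmark {self.index} ({self.name})")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class LandmarkSet:
    """All 22 canonical landmarks of one face plus its label.

    Invariants: every canonical index present exactly once, and the
    inner-eye-corner distance (points 8-9, the normalizer of all
    distance features) strictly positive.
    """

    subject_id: str
    expression: Expression
    points: Dict[int, Landmark] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = sorted(set(CANONICAL_NAMES) - set(self.points))
        if missing:
            names = ", ".join(f"{i} ({CANONICAL_NAMES[i]})" for i in missing)
            raise ValueError(f"LandmarkSet for {self.subject_id!r} missing landmarks: {names}")
        extra = sorted(set(self.points) - set(CANONICAL_NAMES))
        if extra:
            raise ValueError(f"LandmarkSet for {self.subject_id!r} has non-canonical indices {extra}")
        if not np.linalg.norm(self.points[8].xyz - self.points[9].xyz) > 0:
            raise ValueError(
                f"LandmarkSet for {self.subject_id!r}: landmarks 8 and 9 coincide; "
                "the distance normalizer would be zero"
            )

    @classmethod
    def from_array(
        cls, coords: np.ndarray, subject_id: str = "", expression: Expression = Expression.NEUTRAL
    ) -> "LandmarkSet":
        """Build from a (22, 3) array ordered by canonical index."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (N_LANDMARKS, 3):
            raise ValueError(f"expected shape (22, 3), got {coords.shape}")
        pts = {
            i: Landmark(i, CANONICAL_NAMES[i], *coords[i - 1]) for i in range(1, N_LANDMARKS + 1)
        }
        return cls(subject_id=subject_id, expression=expression, points=pts)

    def to_array(self) -> np.ndarray:
        """(22, 3) coordinate array ordered by canonical index."""
        return np.array([self.points[i].xyz for i in range(1, N_LANDMARKS + 1)])

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn`` ((n,3) array -> (n,3) array) to all coordinates."""
        return LandmarkSet.from_array(fn(self.to_array()), self.subject_id, self.expression)

    def __getitem__(self, index: int) -> Landmark:
        return self.points[index]


def as_array_collection(sets: Iterable[LandmarkSet]) -> np.ndarray:
    """Stack landmark sets into an (n_faces, 22, 3) array."""
    return np.stack([ls.to_array() for ls in sets])
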