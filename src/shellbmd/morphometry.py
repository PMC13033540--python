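"""Linear shell measurements and height-to-width ratios.

Landmarks are user-supplied physical coordinates (mm); the package
computes Euclidean distances and the three dimensionless ratios used to
summarize shell shape: gular scute H/W, shoulder-girdle H/W and
maximum-diameter ("total") H/W.  Gular measurements concern the scute
only; shoulder/total are external shell dimensions — the locations are
distinct enums so they cannot be mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LandmarkPair", "MorphometricSet", "measure_distance", "compute_ratios"]

LOCATIONS = ("gular", "shoulder", "total")
AXES = ("height", "width", "length")


@dataclass(frozen=True)
class LandmarkPair:
    """Two physical endpoints defining one linear measurement."""

    location: str
    axis: str
    endpoints: tuple[tuple[float, float, float], tuple[float, float, float]]

    def __post_init__(self):
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.axis == "length" and self.location != "total":
            raise ValueError("length is measured only for the total (carapace) location")
        p0, p1 = (np.asarray(p, dtype=float) for p in self.endpoints)
        if not (np.all(np.isfinite(p0)) and np.all(np.isfinite(p1))):
            raise ValueError("endpoints must be finite")


@dataclass
class MorphometricSet:
    """Per-location heights/widths (mm), carapace length, and H/W ratios."""

    heights_mm: dict[str, float] = field(default_factory=dict)
    widths_mm: dict[str, float] = field(default_factory=dict)
    length_mm: float | None = None
    ratios: dict[str, float] = field(default_factory=dict)


def measure_distance(pair: LandmarkPair, spacing_mm=None) -> float:
    """Euclidean distance between the endpoints in mm.

    If ``spacing_mm`` is given the endpoints are interpreted as voxel
    indices and scaled per axis first (anisotropic grids supported).
    """
    p0, p1 = (np.asarray(p, dtype=float) for p in pair.endpoints)
    if spacing_mm is not None:
        sp = np.asarray(spacing_mm, dtype=float)
        p0, p1 = p0 * sp, p1 * sp
    d = float(np.linalg.norm(p1 - p0))
    if d == 0:
        raise ValueError("coincident endpoints give a zero-length measurement")
    return d


def compute_ratios(pairs: list[LandmarkPair], spacing_mm=None) -> MorphometricSet:
    """Distances for every landmark pair and H/W ratio per location.

    A location missing its height or width simply yields no ratio
    (absent, not an error); a zero width is a validation error.
    """
    result = MorphometricSet()
    for pair in pairs:
        d = measure_distance(pair, spacing_mm=spacing_mm)
        if pair.axis == "height":
            result.heights_mm[pair.location] = d
        elif pair.axis == "width":
            result.widths_mm[pair.location] = d
        else:
            result.length_mm = d
    for loc in LOCATIONS:
        h = result.heights_mm.get(loc)
        w = result.widths_mm.get(loc)
        if h is None or w is None:
            continue
        if w == 0:
            raise ValueError(f"zero width at {loc}")
        result.ratios[loc] = h / w
    return result
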