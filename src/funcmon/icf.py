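"""Linking of assessment scores to ICF qualifiers and qualifier-change detection.

The ICF (International Classification of Functioning, Disability and
Health) grades impairment with qualifiers 0 (no impairment) to 4
(complete impairment). Two mobility assessments are linked:

* SPPB (Short Physical Performance Battery, 0-12 points, higher = better)
  maps directly onto the five qualifier levels.
* TUG (Timed Up & Go, seconds) is first discretised into ordinal
  categories 1-4 by ascending second thresholds, then mapped to a
  qualifier. The default band edges (10, 20, 40 s) and the category map
  {1: 0, 2: 2, 3: 3, 4: 4} are configurable: the published linking fixes
  the worked case (category 2 -> qualifier 2) but not every band edge.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from .core import Direction

#: SPPB points -> ICF qualifier: 12-10 none, 9-7 mild, 6-4 moderate,
#: 3-1 severe, 0 complete.
DEFAULT_SPPB_MAP = {
    12: 0, 11: 0, 10: 0,
    9: 1, 8: 1, 7: 1,
    6: 2, 5: 2, 4: 2,
    3: 3, 2: 3, 1: 3,
    0: 4,
}

#: Ascending TUG second-thresholds separating categories 1|2|3|4.
DEFAULT_TUG_BANDS = (10.0, 20.0, 40.0)

#: TUG category -> ICF qualifier. Qualifier 1 is unused by default; the
#: published worked example forces category 2 -> qualifier 2.
DEFAULT_TUG_MAP = {1: 0, 2: 2, 3: 3, 4: 4}


@dataclass(frozen=True)
class IcfLinkTable:
    """Configurable link table from assessment scores to ICF qualifiers."""

    sppb_map: dict = field(default_factory=lambda: dict(DEFAULT_SPPB_MAP))
    tug_bands: Tuple[float, ...] = DEFAULT_TUG_BANDS
    tug_map: dict = field(default_factory=lambda: dict(DEFAULT_TUG_MAP))

    def __post_init__(self) -> None:
        if set(self.sppb_map) != set(range(13)):
            raise ValueError("sppb_map must be total on 0..12")
        if not all(q in range(5) for q in self.sppb_map.values()):
            raise ValueError("ICF qualifiers must be in 0..4")
        # higher SPPB (better function) must never map to a worse qualifier
        for a in range(12):
            if self.sppb_map[a + 1] > self.sppb_map[a]:
                raise ValueError("sppb_map must be non-increasing in SPPB")
        bands = tuple(float(b) for b in self.tug_bands)
        if any(b2 <= b1 for b1, b2 in zip(bands, bands[1:])):
            raise ValueError("tug_bands must be strictly ascending")
        object.__setattr__(self, "tug_bands", bands)
        n_cat = len(bands) + 1
        if set(self.tug_map) != set(range(1, n_cat + 1)):
            raise ValueError(f"tug_map must be total on 1..{n_cat}")
        if not all(q in range(5) for q in self.tug_map.values()):
            raise ValueError("ICF qualifiers must be in 0..4")

    @classmethod
    def from_dict(cls, d: dict) -> "IcfLinkTable":
        kwargs = {}
        if "sppb_map" in d:
            kwargs["sppb_map"] = {int(k): int(v) for k, v in d["sppb_map"].items()}
        if "tug_bands" in d:
            kwargs["tug_bands"] = tuple(float(b) for b in d["tug_bands"])
        if "tug_map" in d:
            kwargs["tug_map"] = {int(k): int(v) for k, v in d["tug_map"].items()}
        return cls(**kwargs)


def sppb_to_icf(sppb: int, table: Optional[IcfLinkTable] = None) -> int:
    """Map an SPPB total (0-12) to its ICF qualifier (0-4)."""
    table = table or IcfLinkTable()
    if sppb not in table.sppb_map:
        raise ValueError(f"SPPB must be an integer in [0, 12], got {sppb!r}")
    return table.sppb_map[sppb]


def tug_seconds_to_category(
    tug_seconds: float, bands: Optional[Sequence[float]] = None
) -> int:
    """Discretise a TUG time into its ordinal category.

    The category is 1 plus the number of band thresholds strictly below
    the measured time (a time equal to an edge stays in the faster
    category), capped by the number of bands.
    """
    if tug_seconds is None or not tug_seconds > 0:
        raise ValueError(f"TUG seconds must be > 0, got {tug_seconds!r}")
    bands = tuple(bands) if bands is not None else DEFAULT_TUG_BANDS
    return 1 + bisect_left(bands, float(tug_seconds))


def tug_category_to_icf(category: int, table: Optional[IcfLinkTable] = None) -> int:
    """Map a TUG category (1-4) to its ICF qualifier."""
    table = table or IcfLinkTable()
    if category not in table.tug_map:
        raise ValueError(f"TUG category must be in {sorted(table.tug_map)}, got {category!r}")
    return table.tug_map[category]


def icf_change(prev: int, new: int) -> "tuple[int, Optional[Direction]]":
    """Compare two ICF qualifiers; lower qualifier = less impairment.

    Returns ``(changed, direction)`` where changed is 1 iff the
    qualifiers differ and direction is improvement when the new
    qualifier is lower, deterioration when higher, ``None`` otherwise.
    """
    for q in (prev, new):
        if q not in range(5):
            raise ValueError(f"ICF qualifier must be in 0..4, got {q!r}")
    if new == prev:
        return 0, None
    return 1, (Direction.IMPROVEMENT if new < prev else Direction.DETERIORATION)
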