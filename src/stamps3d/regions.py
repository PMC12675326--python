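"""Canonical anatomical region labels and name normalisation.

The plantar surface is segmented into 11 anatomical regions following the
Pedar-style multimask layout (hallux, 2nd toe, toes 3-5, the five metatarsal
heads, medial/lateral midfoot, heel); ``global`` denotes their union.  The
declared order is also the precedence order used to resolve points that fall
exactly on a shared region boundary.
"""

from __future__ import annotations

import re

from .errors import UnmappedRegion

#: Anatomical regions in declared (precedence) order.
REGIONS: tuple[str, ...] = (
    "hallux",
    "toe2",
    "toes3_5",
    "mth1",
    "mth2",
    "mth3",
    "mth4",
    "mth5",
    "midfoot_medial",
    "midfoot_lateral",
    "heel",
)

GLOBAL = "global"
OUTSIDE = "outside"

#: All labels a study table may carry.
ALL_LABELS: tuple[str, ...] = REGIONS + (GLOBAL,)

_SYNONYMS = {
    "global": GLOBAL,
    "total": GLOBAL,
    "hallux": "hallux",
    "1sttoe": "hallux",
    "bigtoe": "hallux",
    "toe1": "hallux",
    "2ndtoe": "toe2",
    "toe2": "toe2",
    "secondtoe": "toe2",
    "toes35": "toes3_5",
    "toes3to5": "toes3_5",
    "toe35": "toes3_5",
    "lessertoes": "toes3_5",
    "medialmidfoot": "midfoot_medial",
    "midfootmedial": "midfoot_medial",
    "lateralmidfoot": "midfoot_lateral",
    "midfootlateral": "midfoot_lateral",
    "heel": "heel",
}
for _i in range(1, 6):
    _ordinal = {1: "1st", 2: "2nd", 3: "3rd", 4: "4th", 5: "5th"}[_i]
    for _alias in (
        f"mth{_i}",
        f"{_ordinal}mth",
        f"{_ordinal}metatarsalhead",
        f"{_ordinal}metatarsal",
        f"metatarsalhead{_i}",
        f"mt{_i}",
    ):
        _SYNONYMS[_alias] = f"mth{_i}"


def canonical_region(name: str) -> str:
    """Map a free-form region name ('1st MTH', 'MTH1', ...) to its canonical label.

    Raises
    ------
    UnmappedRegion
        If the name matches no known synonym.
    """
    key = re.sub(r"[^a-z0-9]", "", name.strip().lower())
    # strip trailing dashes already removed; normalise '3-5' forms
    try:
        return _SYNONYMS[key]
    except KeyError:
        raise UnmappedRegion(f"unmapped region: {name!r}") from None
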