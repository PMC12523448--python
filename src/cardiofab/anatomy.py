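"""Registry of the ten cardiac substructures.

The package models the heart as ten labeled regions: the four chambers
(left/right atria, left/right ventricles), the two venae cavae, the
pulmonary artery and vein, and the ascending/descending aorta.  Label
code 0 is background.  The size grouping drives the two-stage
segmentation cascade: chambers and arteries are "large" targets handled
by the coarse network, while the thin veins (SVC, IVC, PV) are the
"small" refinement targets.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SubstructureID:
    """One of the ten cardiac substructures.

    Attributes
    ----------
    code : int
        Integer label in 1..10 used in label maps (0 is background).
    abbrev : str
        Clinical abbreviation (LA, RA, LV, RV, SVC, IVC, PA, PV, AA, DA).
    size_class : str
        ``"large"`` (chambers + arteries) or ``"small"`` (veins).
    """

    code: int
    abbrev: str
    size_class: str

    def __post_init__(self) -> None:
        if not 1 <= self.code <= 10:
            raise ValueError(f"substructure code must be 1..10, got {self.code}")
        if self.size_class not in ("large", "small"):
            raise ValueError(f"size_class must be 'large' or 'small'")


_DEFS = [
    (1, "LA", "large"),
    (2, "RA", "large"),
    (3, "LV", "large"),
    (4, "RV", "large"),
    (5, "SVC", "small"),
    (6, "IVC", "small"),
    (7, "PA", "large"),
    (8, "PV", "small"),
    (9, "AA", "large"),
    (10, "DA", "large"),
]

SUBSTRUCTURES: tuple[SubstructureID, ...] = tuple(
    SubstructureID(c, a, s) for c, a, s in _DEFS
)

BY_CODE: dict[int, SubstructureID] = {s.code: s for s in SUBSTRUCTURES}
BY_ABBREV: dict[str, SubstructureID] = {s.abbrev: s for s in SUBSTRUCTURES}

LARGE_CODES: tuple[int, ...] = tuple(s.code for s in SUBSTRUCTURES if s.size_class == "large")
SMALL_CODES: tuple[int, ...] = tuple(s.code for s in SUBSTRUCTURES if s.size_class == "small")

#: Vessel -> chamber the vessel drains into / arises from (6-connectivity is
#: guaranteed by the phantom generator).  DA is a free posterior tube.
ATTACHMENTS: dict[str, str | None] = {
    "SVC": "RA",
    "IVC": "RA",
    "PV": "LA",
    "PA": "RV",
    "AA": "LV",
    "DA": None,
}

#: Reference landmark diameters of the digital model, in millimetres.
DEFAULT_DIAMETERS_MM: dict[str, float] = {
    "LA": 35.75,
    "RA": 33.15,
    "LV": 45.63,
    "RV": 36.15,
    "SVC": 18.38,
    "IVC": 21.5,
    "PA": 24.95,
    "PV": 12.2,
    "AA": 30.48,
    "DA": 20.33,
}


def substructure(key: int | str | SubstructureID) -> SubstructureID:
    """Look up a substructure by code, abbreviation, or identity."""
    if isinstance(key, SubstructureID):
        return key
    if isinstance(key, str):
        try:
            return BY_ABBREV[key.upper()]
        except KeyError:
            raise KeyError(f"unknown substructure abbreviation {key!r}") from None
    try:
        return BY_CODE[int(key)]
    except (KeyError, ValueError):
        raise KeyError(f"unknown substructure code {key!r}") from None
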