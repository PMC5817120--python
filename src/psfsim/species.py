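"""Species roster and soil-type constants for the Methow valley shrub-steppe system.

Three long-lived native bunchgrasses and three short-lived non-natives are
tracked throughout.  Soil types are named after the species that cultivated
them during the conditioning phase; the two native grasses that failed to
dominate their conditioning plots (FEID, KOCR) have no soil of their own, and
their plots instead contributed to the naturally recruiting "Mixed" soil.
"""

from __future__ import annotations

from dataclasses import dataclass

NATIVE: tuple[str, ...] = ("PSSP", "FEID", "KOCR")
NON_NATIVE: tuple[str, ...] = ("BRTE", "CEDI", "SILO")
SPECIES: tuple[str, ...] = NATIVE + NON_NATIVE

#: Soil treatments realised by the conditioning phase: one native soil, three
#: non-native soils and one mixed soil.
SOIL_TYPES: tuple[str, ...] = ("PSSP", "BRTE", "CEDI", "SILO", "Mixed")

COMMUNITIES: tuple[str, str] = ("native", "non-native")

#: Percent ground cover of each species in its origin's home field type
#: (natives in never-tilled fields, non-natives in abandoned-agricultural
#: fields), from the landscape vegetation survey.
LANDSCAPE_COVER: dict[str, float] = {
    "PSSP": 18.9,
    "FEID": 2.9,
    "KOCR": 0.2,
    "BRTE": 4.5,
    "CEDI": 5.1,
    "SILO": 3.0,
}

#: Which soil type each species cultivates while it grows.  All native soils
#: are attributed to the dominant native, P. spicata, because FEID/KOCR soils
#: were never realised in the conditioning phase.
SPECIES_TO_SOIL: dict[str, str] = {
    "PSSP": "PSSP",
    "FEID": "PSSP",
    "KOCR": "PSSP",
    "BRTE": "BRTE",
    "CEDI": "CEDI",
    "SILO": "SILO",
}

#: "Self" soil used for the single-rate null model.  Species with a
#: conspecific-cultivated soil use it; FEID and KOCR fall back to the Mixed
#: soil, the community-level "self" soil that their conditioning plots formed.
SELF_SOIL: dict[str, str] = {
    "PSSP": "PSSP",
    "BRTE": "BRTE",
    "CEDI": "CEDI",
    "SILO": "SILO",
    "FEID": "Mixed",
    "KOCR": "Mixed",
}


@dataclass(frozen=True)
class SpeciesInfo:
    """One target species: code, origin group and landscape abundance."""

    code: str
    origin: str  # "native" | "non-native"
    landscape_cover: float  # percent ground cover in the origin's home fields

    def __post_init__(self) -> None:
        if self.origin not in COMMUNITIES:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.landscape_cover < 0:
            raise ValueError("landscape_cover must be >= 0")


SPECIES_INFO: tuple[SpeciesInfo, ...] = tuple(
    SpeciesInfo(code, "native" if code in NATIVE else "non-native", LANDSCAPE_COVER[code])
    for code in SPECIES
)


def origin_of(code: str) -> str:
    """Return "native" or "non-native" for a species code."""
    if code in NATIVE:
        return "native"
    if code in NON_NATIVE:
        return "non-native"
    raise KeyError(f"unknown species code {code!r}")


def community_members(community: str) -> tuple[str, ...]:
    if community == "native":
        return NATIVE
    if community == "non-native":
        return NON_NATIVE
    raise KeyError(f"unknown community {community!r}")
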