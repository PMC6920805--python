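"""Domain model for rhizosphere isolate screening data.

The screening campaign handles four culture-defined functional groups of
rhizosphere bacteria (mesophilic, spore-forming, pseudomonads,
actinobacteria), four qualitative plant-growth-promotion traits scored as
positive/negative per replicate, and three quantitative assays measured on
replicate cultures. Isolate identifiers carry a single-letter group suffix
(e.g. ``36M``, ``19B``, ``6P``, ``12A``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class FunctionalGroup(str, Enum):
    """Culture-defined functional group of a rhizosphere isolate."""

    MESOPHILIC = "mesophilic"
    SPORE_FORMING = "spore_forming"
    PSEUDOMONADS = "pseudomonads"
    ACTINOBACTERIA = "actinobacteria"

    @property
    def suffix(self) -> str:
        """Single-letter isolate-id suffix conventionally used for this group."""
        return _GROUP_SUFFIX[self]

    @classmethod
    def from_suffix(cls, letter: str) -> "FunctionalGroup":
        try:
            return _SUFFIX_GROUP[letter.upper()]
        except KeyError:
            raise ValueError(f"no functional group with suffix {letter!r}") from None


_GROUP_SUFFIX = {
    FunctionalGroup.MESOPHILIC: "M",
    FunctionalGroup.SPORE_FORMING: "B",
    FunctionalGroup.PSEUDOMONADS: "P",
    FunctionalGroup.ACTINOBACTERIA: "A",
}
_SUFFIX_GROUP = {v: k for k, v in _GROUP_SUFFIX.items()}


class QualitativeTrait(str, Enum):
    """First-stage screening traits scored positive/negative per replicate."""

    P_SOLUBILIZATION = "p_solubilization"
    SIDEROPHORES = "siderophores"
    AMMONIUM = "ammonium"
    NITRIFICATION_QUAL = "nitrification_qual"


class QuantParameter(str, Enum):
    """Second-stage quantitative assay parameters.

    Units: µM for phosphate mineralization and nitrification
    (NO2-/NO3- accumulation), µg/mL for indole-3-acetic acid.
    """

    P_MINERALIZATION = "p_mineralization"
    IAA = "iaa"
    NITRIFICATION = "nitrification"


# Canonical orderings used for matrices and tables.
TRAIT_ORDER: tuple[QualitativeTrait, ...] = tuple(QualitativeTrait)
PARAMETER_ORDER: tuple[QuantParameter, ...] = tuple(QuantParameter)
GROUP_ORDER: tuple[FunctionalGroup, ...] = tuple(FunctionalGroup)


@dataclass
class IsolateRecord:
    """One isolate with its replicate-level screening results.

    ``phenotype`` maps each performed qualitative trait to a non-empty list
    of per-replicate boolean outcomes; ``quant`` maps each performed
    quantitative assay to a non-empty list of per-replicate non-negative
    values. An assay that was not performed is simply absent from the map —
    never stored as zero.
    """

    isolate_id: str
    group: FunctionalGroup
    viability_ok: bool = True
    phenotype: dict[QualitativeTrait, list[bool]] = field(default_factory=dict)
    quant: dict[QuantParameter, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.isolate_id:
            raise ValueError("isolate_id must be non-empty")
        suffix = self.isolate_id[-1].upper()
        if suffix != self.group.suffix:
            raise ValueError(
                f"isolate {self.isolate_id!r}: suffix {suffix!r} inconsistent "
                f"with group {self.group.value!r} (expected {self.group.suffix!r})"
            )
        for trait, outcomes in self.phenotype.items():
            if not outcomes:
                raise ValueError(
                    f"isolate {self.isolate_id!r}: empty replicate list for "
                    f"{trait.value}; an unperformed assay must be absent"
                )
        for param, values in self.quant.items():
            if not values:
                raise ValueError(
                    f"isolate {self.isolate_id!r}: empty replicate list for "
                    f"{param.value}; an unperformed assay must be absent"
                )
            for v in values:
                if v < 0:
                    raise ValueError(
                        f"isolate {self.isolate_id!r}: negative value {v} for "
                        f"{param.value}"
                    )


@dataclass
class GrowthRecord:
    """One growth-chamber pot: treatment label, dry biomass (g) and height (cm)."""

    pot_id: str
    treatment: str  # isolate_id or "control"
    biomass_dry_matter: float
    height: float

    def __post_init__(self) -> None:
        if self.biomass_dry_matter <= 0:
            raise ValueError(f"pot {self.pot_id!r}: biomass must be > 0")
        if self.height <= 0:
            raise ValueError(f"pot {self.pot_id!r}: height must be > 0")


CONTROL_TREATMENT = "control"
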