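"""Published worked example from the durum wheat rhizosphere screening campaign.

These tables are the printed results of the screening study the pipeline
implements: the functional-group isolate counts, the per-group qualitative
positivity rates, the population quartile summaries of the three
quantitative assays, the per-isolate quantitative means of the shortlisted
strains, and the published ordinal codes and round-by-round selection
lists. They serve as reproduction fixtures and as calibration defaults for
the synthetic-data generator.

Known internal inconsistencies of the published tables (kept here as
printed, never "corrected"):

* the pseudomonad P-mineralization quartile row (q1 = 0, median = 0.91,
  q3 = 0) violates q1 <= median <= q3 and is represented with the
  ``allow_invalid`` override; it is excluded from generator calibration;
* isolate 60M is printed with codes for P-mineralization and IAA although
  no value is printed for either assay, and its nitrification value
  (17.56) sits above the group third quartile (17.51) yet is coded 1;
* isolate 20P is printed with IAA code 1 without a printed IAA value, and
  its nitrification value (15.82) sits just below the group median
  (15.83) yet is coded 2 — consistent with rounding of an unrounded
  underlying value.

``DISCORDANT_CELLS`` lists those cells; every other printed code is
reproduced exactly by the quartile coding rule.
"""

from __future__ import annotations

from .coding import QuartileSummary
from .records import FunctionalGroup, IsolateRecord, QualitativeTrait, QuantParameter

_M = FunctionalGroup.MESOPHILIC
_B = FunctionalGroup.SPORE_FORMING
_P = FunctionalGroup.PSEUDOMONADS
_A = FunctionalGroup.ACTINOBACTERIA

P_MIN = QuantParameter.P_MINERALIZATION
IAA = QuantParameter.IAA
NIT = QuantParameter.NITRIFICATION

#: Number of isolates per functional group.
GROUP_SIZES: dict[FunctionalGroup, int] = {_M: 133, _B: 96, _P: 65, _A: 180}

#: Number of quantitative assay parameters of the second stage.
N_QUANT_PARAMETERS = 3

#: Fraction of isolates positive per (group, qualitative trait). Where the
#: study reports only a range for a pair of groups, the assignment within
#: the range is a fixed representative choice.
POSITIVITY: dict[tuple[FunctionalGroup, QualitativeTrait], float] = {
    (_M, QualitativeTrait.P_SOLUBILIZATION): 0.41,
    (_B, QualitativeTrait.P_SOLUBILIZATION): 0.54,
    (_P, QualitativeTrait.P_SOLUBILIZATION): 0.65,
    (_A, QualitativeTrait.P_SOLUBILIZATION): 0.32,
    (_M, QualitativeTrait.SIDEROPHORES): 0.49,
    (_B, QualitativeTrait.SIDEROPHORES): 0.68,
    (_P, QualitativeTrait.SIDEROPHORES): 0.82,
    (_A, QualitativeTrait.SIDEROPHORES): 0.30,
    (_M, QualitativeTrait.AMMONIUM): 0.50,
    (_B, QualitativeTrait.AMMONIUM): 0.68,
    (_P, QualitativeTrait.AMMONIUM): 0.99,
    (_A, QualitativeTrait.AMMONIUM): 0.11,
    (_M, QualitativeTrait.NITRIFICATION_QUAL): 0.20,
    (_B, QualitativeTrait.NITRIFICATION_QUAL): 0.15,
    (_P, QualitativeTrait.NITRIFICATION_QUAL): 0.25,
    (_A, QualitativeTrait.NITRIFICATION_QUAL): 0.13,
}

#: Published population quartile summaries per (group, parameter):
#: (q1, median, q3). Units: µM for P-mineralization and nitrification,
#: µg/mL for IAA.
_QUARTILE_ROWS: dict[tuple[FunctionalGroup, QuantParameter], tuple[float, float, float]] = {
    (_M, P_MIN): (1.12, 1.81, 2.61),
    (_M, IAA): (5.23, 18.86, 38.91),
    (_M, NIT): (1.48, 13.13, 17.51),
    (_B, P_MIN): (0.94, 1.49, 1.79),
    (_B, IAA): (3.75, 5.33, 9.09),
    (_B, NIT): (0.78, 1.62, 1.97),
    (_P, P_MIN): (0.0, 0.91, 0.0),  # printed as-is; violates q1 <= median <= q3
    (_P, IAA): (1.38, 2.27, 3.65),
    (_P, NIT): (8.20, 15.83, 17.32),
    (_A, P_MIN): (0.19, 0.49, 1.61),
    (_A, IAA): (4.25, 7.21, 26.38),
    (_A, NIT): (0.91, 2.44, 8.16),
}

#: (group, parameter) keys whose published quartile row is internally
#: inconsistent; excluded from generator calibration.
INVALID_QUARTILE_ROWS = {(_P, P_MIN)}


def quartile_summaries(
    allow_invalid: bool = False,
) -> dict[tuple[FunctionalGroup, QuantParameter], QuartileSummary]:
    """Published quartile summaries as QuartileSummary objects.

    The internally inconsistent pseudomonad P-mineralization row is only
    included when ``allow_invalid=True``; reproduction runs that need the
    full published table must opt in explicitly.
    """
    out = {}
    for key, (q1, med, q3) in _QUARTILE_ROWS.items():
        invalid = key in INVALID_QUARTILE_ROWS
        if invalid and not allow_invalid:
            continue
        out[key] = QuartileSummary(
            group=key[0], parameter=key[1], q1=q1, median=med, q3=q3,
            allow_invalid=invalid,
        )
    return out


#: Published per-isolate quantitative assay means of the shortlisted
#: strains (None = assay not assessed, printed "/").
WORKED_VALUES: dict[str, dict[QuantParameter, float | None]] = {
    "36M": {P_MIN: 4.90, IAA: 0.98, NIT: 0.99},
    "40M": {P_MIN: 4.79, IAA: None, NIT: None},
    "50M": {P_MIN: 2.15, IAA: 0.98, NIT: 1.99},
    "54M": {P_MIN: None, IAA: None, NIT: 17.88},
    "58M": {P_MIN: None, IAA: None, NIT: 18.41},
    "60M": {P_MIN: None, IAA: None, NIT: 17.56},
    "97M": {P_MIN: 8.90, IAA: None, NIT: None},
    "3B": {P_MIN: 2.89, IAA: 2.96, NIT: 0.40},
    "19B": {P_MIN: 1.48, IAA: 5.72, NIT: 7.18},
    "6P": {P_MIN: None, IAA: None, NIT: 17.60},
    "20P": {P_MIN: None, IAA: None, NIT: 15.82},
    "23P": {P_MIN: 2.17, IAA: 3.65, NIT: None},
    "10A": {P_MIN: None, IAA: None, NIT: 18.69},
    "12A": {P_MIN: 8.01, IAA: 5.82, NIT: None},
    "25A": {P_MIN: 3.96, IAA: None, NIT: None},
    "145A": {P_MIN: None, IAA: 140.31, NIT: None},
}

#: Published ordinal codes (P-mineralization, IAA, nitrification) of the
#: first- and second-round selected isolates.
PUBLISHED_CODES: dict[str, tuple[int, int, int]] = {
    # first round
    "36M": (3, 1, 1),
    "40M": (3, 0, 0),
    "97M": (3, 0, 0),
    "54M": (0, 0, 3),
    "58M": (0, 0, 3),
    "114M": (0, 3, 0),
    "3B": (3, 1, 1),
    "19B": (1, 2, 3),
    "45B": (0, 3, 0),
    "89B": (0, 3, 0),
    "6P": (0, 0, 3),
    "10A": (0, 0, 3),
    "12A": (3, 1, 0),
    "25A": (3, 0, 0),
    "145A": (0, 3, 0),
    # second round
    "50M": (2, 1, 1),
    "60M": (2, 1, 1),
    "20P": (0, 1, 2),
    "23P": (3, 3, 0),
}

FIRST_ROUND_IDS = [
    "36M", "40M", "97M", "54M", "58M", "114M", "3B", "19B", "45B", "89B",
    "6P", "10A", "12A", "25A", "145A",
]
SECOND_ROUND_IDS = ["50M", "60M", "20P", "23P"]
#: Isolates excluded for viability loss during cold storage.
EXCLUDED_IDS = ["114M", "45B", "89B"]

#: Printed code cells that the quartile coding rule cannot reproduce from
#: the printed values (see module docstring).
DISCORDANT_CELLS: set[tuple[str, QuantParameter]] = {
    ("20P", IAA),
    ("20P", NIT),
    ("60M", P_MIN),
    ("60M", IAA),
    ("60M", NIT),
}


def worked_example_records() -> list[IsolateRecord]:
    """The shortlisted isolates as records (published means, one replicate).

    The three low-viability first-round isolates carry no printed
    quantitative values; they appear with ``viability_ok=False`` and empty
    assay maps.
    """
    records = []
    for iso_id in list(WORKED_VALUES) + EXCLUDED_IDS:
        group = FunctionalGroup.from_suffix(iso_id[-1])
        quant = {
            param: [value]
            for param, value in WORKED_VALUES.get(iso_id, {}).items()
            if value is not None
        }
        records.append(
            IsolateRecord(
                isolate_id=iso_id,
                group=group,
                viability_ok=iso_id not in EXCLUDED_IDS,
                quant=quant,
            )
        )
    return records


def screening_workload() -> dict[str, int]:
    """Planned second-stage assay count: every isolate x every parameter."""
    n_isolates = sum(GROUP_SIZES.values())
    return {
        "n_isolates": n_isolates,
        "n_parameters": N_QUANT_PARAMETERS,
        "planned_assays": n_isolates * N_QUANT_PARAMETERS,
    }


def selection_accounting() -> dict[str, object]:
    """Round-by-round head counts of the published selection."""
    by_group = {g: 0 for g in FunctionalGroup}
    for iso in FIRST_ROUND_IDS:
        by_group[FunctionalGroup.from_suffix(iso[-1])] += 1
    final = [
        i for i in FIRST_ROUND_IDS + SECOND_ROUND_IDS if i not in EXCLUDED_IDS
    ]
    return {
        "n_first_round": len(FIRST_ROUND_IDS),
        "first_round_by_group": by_group,
        "n_second_round": len(SECOND_ROUND_IDS),
        "n_excluded": len(EXCLUDED_IDS),
        "final_ids": final,
        "n_final": len(final),
    }
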