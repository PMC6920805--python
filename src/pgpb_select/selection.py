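"""Stage 2c — the selection rules.

First round: within each functional group and assay parameter, isolates
coded 3 (at or above the population third quartile) are candidates, and
among them only those sharing the top Tukey homogeneous-group letter —
i.e. not significantly below the best candidate — are selected. Second
round: isolates not yet selected but showing at least two traits (code >= 1
in two or more parameters) are added. Finally, isolates that lost
viability in cold storage are excluded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .records import (
    GROUP_ORDER,
    PARAMETER_ORDER,
    FunctionalGroup,
    IsolateRecord,
    QuantParameter,
)
from .stats import tukey_letters

_GROUP_PHRASE = {
    FunctionalGroup.MESOPHILIC: "mesophilic bacteria",
    FunctionalGroup.SPORE_FORMING: "spore-forming bacteria",
    FunctionalGroup.PSEUDOMONADS: "pseudomonads",
    FunctionalGroup.ACTINOBACTERIA: "actinobacteria",
}
_PARAM_PHRASE = {
    QuantParameter.P_MINERALIZATION: "P",
    QuantParameter.IAA: "IAA",
    QuantParameter.NITRIFICATION: "Nit",
}


def isolate_sort_key(isolate_id: str) -> tuple[int, str]:
    """Natural ordering: numeric stem first, then group suffix."""
    m = re.match(r"(\d+)", isolate_id)
    return (int(m.group(1)) if m else 0, isolate_id)


@dataclass
class SelectionReport:
    """Round-by-round selection outcome with the rule that fired per entry."""

    first_round: list[tuple[str, QuantParameter, str]] = field(default_factory=list)
    second_round: list[tuple[str, str]] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)
    final: list[str] = field(default_factory=list)

    @property
    def selected_ids(self) -> set[str]:
        return {e[0] for e in self.first_round} | {e[0] for e in self.second_round}


def first_round(
    codes: pd.DataFrame,
    records: Iterable[IsolateRecord],
    alpha: float = 0.05,
    compare_all: bool = False,
) -> list[tuple[str, QuantParameter, str]]:
    """Per (group, parameter) code-3 candidates pruned to the top Tukey letter.

    ``codes`` is the isolate x parameter ordinal table; ``records`` supply
    the QC-kept replicate values the ANOVA runs on. With ``compare_all``
    the homogeneous groups are computed over every assayed isolate of the
    group rather than over the code-3 candidates only. A single candidate
    is selected without a comparison; candidates lacking the >= 2 replicates
    an ANOVA needs are all retained.
    """
    by_id = {r.isolate_id: r for r in records}
    entries: list[tuple[str, QuantParameter, str]] = []
    for group in GROUP_ORDER:
        members = sorted(
            (i for i in codes.index if by_id[i].group == group), key=isolate_sort_key
        )
        for param in PARAMETER_ORDER:
            candidates = [i for i in members if codes.loc[i, param.value] == 3]
            if not candidates:
                continue
            rule = (
                f"highest level of {_PARAM_PHRASE[param]} among "
                f"{_GROUP_PHRASE[group]}"
            )
            if len(candidates) == 1:
                entries.append((candidates[0], param, rule + " (single candidate)"))
                continue
            scope = members if compare_all else candidates
            samples = {
                i: by_id[i].quant[param]
                for i in scope
                if param in by_id[i].quant
            }
            if any(len(v) < 2 for v in samples.values()) or len(samples) < 2:
                entries.extend(
                    (i, param, rule + " (no replicate comparison possible)")
                    for i in candidates
                )
                continue
            grouping = tukey_letters(samples, alpha=alpha)
            top = grouping.top_letter()
            entries.extend(
                (i, param, rule)
                for i in candidates
                if top in grouping.letters[i]
            )
    return entries


def second_round(
    codes: pd.DataFrame,
    already_selected: set[str],
    min_traits: int = 2,
) -> list[tuple[str, str]]:
    """Add not-yet-selected isolates showing >= ``min_traits`` coded traits."""
    entries = []
    for iso in sorted(codes.index, key=isolate_sort_key):
        if iso in already_selected:
            continue
        n_traits = int((codes.loc[iso] >= 1).sum())
        if n_traits >= min_traits:
            entries.append((iso, f"{n_traits} properties at level >= 1"))
    return entries


def viability_filter(
    first_round_entries: list[tuple[str, QuantParameter, str]],
    second_round_entries: list[tuple[str, str]],
    records: Iterable[IsolateRecord],
) -> SelectionReport:
    """Assemble the report, excluding isolates that failed cold-storage viability."""
    by_id = {r.isolate_id: r for r in records}
    report = SelectionReport(
        first_round=list(first_round_entries), second_round=list(second_round_entries)
    )
    selected = sorted(report.selected_ids, key=isolate_sort_key)
    for iso in selected:
        if iso in by_id and not by_id[iso].viability_ok:
            report.excluded.append((iso, "viability loss in cold storage"))
    excluded_ids = {e[0] for e in report.excluded}
    report.final = [i for i in selected if i not in excluded_ids]
    return report


def run_selection(
    records: Iterable[IsolateRecord],
    summaries: Mapping | None = None,
    alpha: float = 0.05,
    min_traits: int = 2,
    cv_threshold: float = 10.0,
    compare_all: bool = False,
):
    """Full stage-2 pipeline: QC -> quartile summaries -> codes -> rounds.

    Population quartile summaries are computed over the raw pooled
    replicates (pre-QC) unless supplied externally; isolate-level coding
    values are means of QC-kept replicates. Returns
    ``(report, codes, summaries, qc_log)``.
    """
    from .coding import code_table, summaries_from_records
    from .qc import apply_qc

    records = list(records)
    if summaries is None:
        summaries = summaries_from_records(records)
    cleaned, qc_log = apply_qc(records, cv_threshold=cv_threshold)
    codes = code_table(cleaned, summaries)
    fr = first_round(codes, cleaned, alpha=alpha, compare_all=compare_all)
    sr = second_round(codes, {e[0] for e in fr}, min_traits=min_traits)
    report = viability_filter(fr, sr, records)
    return report, codes, summaries, qc_log
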