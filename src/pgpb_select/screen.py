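"""Stage 1 — qualitative screening: binary trait codes and group positivity.

A qualitative assay run in replicate is collapsed to a single binary code:
1 when every replicate is positive, 0 otherwise (all negative, a single
positive replicate, or any mixed outcome). Unanimity is required because a
single positive replicate is treated as non-reproducible. An assay that was
not performed contributes 0 — absence of evidence cannot support selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    TRAIT_ORDER,
    FunctionalGroup,
    IsolateRecord,
    QualitativeTrait,
)


def encode_binary(outcomes: Sequence[bool]) -> int:
    """Collapse per-replicate qualitative outcomes to a 0/1 code.

    Returns 1 iff every replicate is positive; 0 otherwise. An empty list is
    an error — an absent assay must be handled by the caller (as code 0).
    """
    if len(outcomes) == 0:
        raise ValueError("empty replicate list; absent assay must be coded 0 by caller")
    return int(all(outcomes))


@dataclass
class BinaryTraitMatrix:
    """Isolates x qualitative-traits matrix of binary codes (no missing cells)."""

    isolates: list[str]
    traits: list[QualitativeTrait]
    entries: np.ndarray  # shape (n_isolates, n_traits), dtype int, values {0, 1}

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=int)
        if self.entries.shape != (len(self.isolates), len(self.traits)):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.isin(self.entries, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            index=pd.Index(self.isolates, name="isolate_id"),
            columns=[t.value for t in self.traits],
        )


@dataclass
class PositivitySummary:
    """Fraction of isolates of one group coded positive for one trait."""

    group: FunctionalGroup
    trait: QualitativeTrait
    fraction_positive: float
    n_isolates: int


def build_matrix(records: Iterable[IsolateRecord]) -> BinaryTraitMatrix:
    """Binary-code every isolate x trait cell; unperformed assays code 0."""
    records = list(records)
    entries = np.zeros((len(records), len(TRAIT_ORDER)), dtype=int)
    for i, rec in enumerate(records):
        for j, trait in enumerate(TRAIT_ORDER):
            outcomes = rec.phenotype.get(trait)
            entries[i, j] = encode_binary(outcomes) if outcomes else 0
    return BinaryTraitMatrix(
        isolates=[r.isolate_id for r in records],
        traits=list(TRAIT_ORDER),
        entries=entries,
    )


def summarize_positivity(
    matrix: BinaryTraitMatrix, groups: Mapping[str, FunctionalGroup]
) -> list[PositivitySummary]:
    """Per-(group, trait) fraction of positively coded isolates.

    Every isolate in the matrix must be mapped to a group; a group present
    in the mapping's range with zero member isolates is an error.
    """
    unmapped = [i for i in matrix.isolates if i not in groups]
    if unmapped:
        raise ValueError(f"isolates without a group mapping: {unmapped[:5]}")
    present_groups = {groups[i] for i in matrix.isolates}
    member_idx: dict[FunctionalGroup, list[int]] = {g: [] for g in present_groups}
    for idx, iso in enumerate(matrix.isolates):
        member_idx[groups[iso]].append(idx)

    summaries = []
    for group in sorted(present_groups, key=lambda g: g.value):
        rows = matrix.entries[member_idx[group]]
        if rows.shape[0] == 0:
            raise ValueError(f"group {group.value!r} has no isolates")
        for j, trait in enumerate(matrix.traits):
            summaries.append(
                PositivitySummary(
                    group=group,
                    trait=trait,
                    fraction_positive=float(rows[:, j].mean()),
                    n_isolates=int(rows.shape[0]),
                )
            )
    return summaries


def positivity_frame(summaries: list[PositivitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [s.group.value for s in summaries],
            "trait": [s.trait.value for s in summaries],
            "fraction_positive": [s.fraction_positive for s in summaries],
            "n_isolates": [s.n_isolates for s in summaries],
        }
    )
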