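"""Stage 2b — population-quartile ordinal coding of quantitative traits.

Cut-offs are not set a priori: for each functional group and assay
parameter, the median and quartiles of the pooled replicate values of all
isolates define the population trend, and each isolate's value is coded on
a four-level ordinal scale:

* 0 — negative to the assay (not performed, no detectable activity, or 0),
* 1 — positive but below the group median,
* 2 — at or above the median, below the third quartile,
* 3 — at or above the third quartile.

Boundaries are closed on the upper side: a value exactly at the median
codes 2 and a value exactly at the third quartile codes 3, so an isolate
sitting on a cut-off is credited with the higher level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import PARAMETER_ORDER, FunctionalGroup, IsolateRecord, QuantParameter


@dataclass(frozen=True)
class QuartileSummary:
    """First quartile, median and third quartile of one group x parameter.

    Ordering violations (q1 <= median <= q3) are rejected at construction
    unless ``allow_invalid=True`` — the escape hatch exists so externally
    published summary rows containing typographical inconsistencies can
    still be represented in reproduction runs.
    """

    group: FunctionalGroup
    parameter: QuantParameter
    q1: float
    median: float
    q3: float
    allow_invalid: bool = False

    def __post_init__(self) -> None:
        if not self.allow_invalid and not (self.q1 <= self.median <= self.q3):
            raise ValueError(
                f"invalid quartile ordering for {self.group.value}/"
                f"{self.parameter.value}: q1={self.q1}, median={self.median}, "
                f"q3={self.q3}"
            )


def compute_quartiles(
    values: Sequence[float],
    group: FunctionalGroup,
    parameter: QuantParameter,
) -> QuartileSummary:
    """Quartiles of pooled replicate values by linear interpolation.

    Uses linear interpolation between order statistics (the common
    spreadsheet/statistics default). Requires at least 4 values.
    """
    if len(values) < 4:
        raise ValueError("quartiles need at least 4 pooled values")
    q1, med, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return QuartileSummary(
        group=group, parameter=parameter, q1=float(q1), median=float(med), q3=float(q3)
    )


def summaries_from_records(
    records: Iterable[IsolateRecord],
) -> dict[tuple[FunctionalGroup, QuantParameter], QuartileSummary]:
    """Population quartiles per (group, parameter) over pooled replicates."""
    pooled: dict[tuple[FunctionalGroup, QuantParameter], list[float]] = {}
    for rec in records:
        for param, vals in rec.quant.items():
            pooled.setdefault((rec.group, param), []).extend(vals)
    return {
        key: compute_quartiles(vals, key[0], key[1]) for key, vals in pooled.items()
    }


def assign_code(value: float | None, summary: QuartileSummary) -> int:
    """Four-level ordinal code of one assay value against its group summary."""
    if value is None or value <= 0:
        return 0
    if value >= summary.q3:
        return 3
    if value >= summary.median:
        return 2
    return 1


def code_table(
    records: Iterable[IsolateRecord],
    summaries: Mapping[tuple[FunctionalGroup, QuantParameter], QuartileSummary],
) -> pd.DataFrame:
    """Code every isolate x parameter cell; rows indexed by isolate_id.

    The value entering the code is the mean of the isolate's (QC-kept)
    replicates; an absent assay codes 0. A (group, parameter) combination
    present in the data but missing from ``summaries`` is an error.
    """
    records = list(records)
    rows = {}
    for rec in records:
        codes = {}
        for param in PARAMETER_ORDER:
            vals = rec.quant.get(param)
            if vals is None:
                codes[param.value] = 0
                continue
            key = (rec.group, param)
            if key not in summaries:
                raise ValueError(
                    f"no quartile summary for {rec.group.value}/{param.value}"
                )
            codes[param.value] = assign_code(float(np.mean(vals)), summaries[key])
        rows[rec.isolate_id] = codes
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    table.index.name = "isolate_id"
    if len(table) == 0:
        table = pd.DataFrame(
            columns=[p.value for p in PARAMETER_ORDER], dtype=int
        ).rename_axis("isolate_id")
    return table[[p.value for p in PARAMETER_ORDER]]
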