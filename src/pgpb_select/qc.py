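"""Stage 2a — replicate quality control.

Quantitative assay replicates are gated on the coefficient of variation:
triplets with CV at or below the threshold (default 10%) pass untouched;
above it, Dixon's Q test — the standard small-sample outlier test in
analytical chemistry — is applied to the most extreme replicate. A
significant Q removes that single replicate; a non-significant one keeps
all values but flags the set as unresolved. At most one replicate is ever
removed, and no isolate is discarded at this stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

# Dixon's Q (r10) two-sided critical values for n = 3..10.
_DIXON_CRITICAL = {
    0.05: {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493, 10: 0.466},
    0.01: {3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680, 8: 0.634, 9: 0.598, 10: 0.568},
}


@dataclass
class QcOutcome:
    """Result of the CV gate on one replicate set."""

    kept: list[float]
    removed: list[tuple[float, str]] = field(default_factory=list)
    cv_before: float = 0.0
    cv_after: float = 0.0
    flagged_unresolved: bool = False


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV in percent: 100 * sd(n-1) / mean. Needs >= 2 values, mean > 0."""
    if len(values) < 2:
        raise ValueError("CV needs at least 2 values")
    mean = sum(values) / len(values)
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    return 100.0 * math.sqrt(var) / mean


def dixon_q(values: Sequence[float]) -> tuple[float, float]:
    """Dixon's r10 statistic for the most extreme value.

    Returns (Q, suspect_value); Q = gap / range for whichever end of the
    sorted sample has the larger gap to its neighbour.
    """
    if len(values) < 3:
        raise ValueError("Dixon's Q needs at least 3 values")
    s = sorted(values)
    rng = s[-1] - s[0]
    if rng == 0:
        return 0.0, s[-1]
    q_low = (s[1] - s[0]) / rng
    q_high = (s[-1] - s[-2]) / rng
    if q_high >= q_low:
        return q_high, s[-1]
    return q_low, s[0]


def qc_filter(
    values: Sequence[float],
    cv_threshold: float = 10.0,
    alpha: float = 0.05,
    unconditional: bool = False,
) -> QcOutcome:
    """CV gate with Dixon-test-mediated single-outlier removal.

    With ``unconditional=True`` the most extreme replicate is removed
    whenever the CV exceeds the threshold, without requiring Dixon
    significance (an alternative reading of the removal rule).
    """
    values = [float(v) for v in values]
    cv0 = coefficient_of_variation(values)
    if cv0 <= cv_threshold:
        return QcOutcome(kept=values, cv_before=cv0, cv_after=cv0)

    n = len(values)
    if n < 3:
        return QcOutcome(kept=values, cv_before=cv0, cv_after=cv0, flagged_unresolved=True)
    try:
        critical = _DIXON_CRITICAL[alpha][min(n, 10)]
    except KeyError:
        raise ValueError(
            f"no Dixon critical value tabulated for alpha={alpha}"
        ) from None
    if n > 10:
        raise ValueError("Dixon's Q tabulated only up to n = 10")

    q, suspect = dixon_q(values)
    if q > critical or (unconditional and q > 0):
        kept = list(values)
        kept.remove(suspect)
        reason = (
            f"Dixon Q = {q:.3f} > {critical:.3f} (n={n}, alpha={alpha})"
            if q > critical
            else f"unconditional removal (CV {cv0:.1f}% > {cv_threshold}%)"
        )
        cv1 = coefficient_of_variation(kept)
        return QcOutcome(
            kept=kept,
            removed=[(suspect, reason)],
            cv_before=cv0,
            cv_after=cv1,
            flagged_unresolved=cv1 > cv_threshold,
        )
    return QcOutcome(kept=values, cv_before=cv0, cv_after=cv0, flagged_unresolved=True)


def apply_qc(
    records,
    cv_threshold: float = 10.0,
    alpha: float = 0.05,
    unconditional: bool = False,
):
    """Run the CV gate on every isolate x parameter replicate set.

    Returns ``(cleaned_records, log)`` where ``cleaned_records`` is a new
    list of records whose quantitative replicate lists hold only the kept
    values, and ``log`` lists one row per assayed set with the CV before and
    after, any removed value, and the unresolved flag. Single-replicate
    sets (no CV defined) pass through untouched.
    """
    import copy

    import pandas as pd

    cleaned = []
    log_rows = []
    for rec in records:
        new = copy.deepcopy(rec)
        for param, values in rec.quant.items():
            if len(values) < 2:
                continue
            out = qc_filter(
                values, cv_threshold=cv_threshold, alpha=alpha, unconditional=unconditional
            )
            new.quant[param] = out.kept
            log_rows.append(
                {
                    "isolate_id": rec.isolate_id,
                    "parameter": param.value,
                    "cv_before": out.cv_before,
                    "cv_after": out.cv_after,
                    "removed": out.removed[0][0] if out.removed else None,
                    "reason": out.removed[0][1] if out.removed else "",
                    "flagged_unresolved": out.flagged_unresolved,
                }
            )
        cleaned.append(new)
    log = pd.DataFrame(
        log_rows,
        columns=[
            "isolate_id",
            "parameter",
            "cv_before",
            "cv_after",
            "removed",
            "reason",
            "flagged_unresolved",
        ],
    )
    return cleaned, log
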