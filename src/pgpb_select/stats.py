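"""Shared statistics — one-way ANOVA, Tukey HSD, compact letter display.

Both the second selection (alpha = 0.05) and the growth-chamber validation
(alpha = 0.01) compare treatment levels with a one-way fixed-effects ANOVA
followed by Tukey's honestly-significant-difference test, and summarize the
result as "homogeneous groups": levels that are not significantly different
share a letter. Unbalanced designs (replicate counts may differ after QC
removal) use the Tukey-Kramer adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def _validate(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for a in arrays:
        if a.size < 2:
            raise ValueError("every group needs at least 2 values")
    n_total = sum(a.size for a in arrays)
    if n_total - len(arrays) < 1:
        raise ValueError("non-positive residual degrees of freedom")
    return arrays


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA; returns (F, p).

    Degenerate all-equal data (zero between- and within-group variance)
    yields F = 0, p = 1 rather than an undefined ratio.
    """
    arrays = _validate(groups)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    with np.errstate(divide="ignore"):
        f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


@dataclass
class TukeyGrouping:
    """Compact-letter display of Tukey HSD homogeneous groups.

    ``levels`` are ordered by descending mean (label-lexicographic on
    ties); two levels share a letter iff their pairwise comparison is not
    significant at ``alpha``.
    """

    levels: list[str]
    means: dict[str, float]
    letters: dict[str, str]
    alpha: float
    p_values: pd.DataFrame

    def top_letter(self) -> str:
        """Letter of the highest-mean level ('a' by construction)."""
        return self.letters[self.levels[0]][0]


def tukey_pvalues(labelled: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All pairwise Tukey(-Kramer) HSD p-values via the studentized range.

    For levels i, j: q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)),
    referred to the studentized-range distribution with k levels and the
    pooled residual degrees of freedom.
    """
    labels = list(labelled)
    arrays = _validate([labelled[k] for k in labels])
    k = len(labels)
    means = np.array([a.mean() for a in arrays])
    ns = np.array([a.size for a in arrays])
    df = int(ns.sum()) - k
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = sse / df

    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(means[i] - means[j])
            if mse == 0:
                pij = 1.0 if diff == 0 else 0.0
            else:
                q = diff / np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                pij = float(sps.studentized_range.sf(q, k, df))
                pij = min(max(pij, 0.0), 1.0)
            p[i, j] = p[j, i] = pij
    return pd.DataFrame(p, index=labels, columns=labels)


def _compact_letters(
    order: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order`` fixes letter precedence (highest mean first); ``significant``
    holds unordered significant pairs as sorted tuples.
    """
    columns: list[set[str]] = [set(order)]
    for pair in sorted(significant):
        i, j = pair
        new_columns: list[set[str]] = []
        for col in columns:
            if i in col and j in col:
                new_columns.extend([col - {i}, col - {j}])
            else:
                new_columns.append(col)
        # absorb: drop duplicates and proper subsets
        columns = []
        for col in new_columns:
            if any(col < other for other in new_columns) or col in columns:
                continue
            columns.append(col)

    rank = {label: idx for idx, label in enumerate(order)}
    columns.sort(key=lambda col: (min(rank[m] for m in col), sorted(col)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {label: [] for label in order}
    for letter, col in zip(alphabet, columns):
        for member in col:
            letters[member].append(letter)
    return {label: "".join(sorted(ls)) for label, ls in letters.items()}


def tukey_letters(
    labelled: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> TukeyGrouping:
    """Tukey HSD homogeneous groups with deterministic letters.

    Levels are ordered by descending mean, label-lexicographic on ties; the
    highest mean always carries letter 'a'.
    """
    pvals = tukey_pvalues(labelled)
    means = {k: float(np.mean(labelled[k])) for k in labelled}
    order = sorted(means, key=lambda k: (-means[k], k))
    significant = {
        tuple(sorted((i, j)))
        for i in order
        for j in order
        if i < j and pvals.loc[i, j] < alpha
    }
    letters = _compact_letters(order, significant)
    return TukeyGrouping(
        levels=order, means=means, letters=letters, alpha=alpha, p_values=pvals
    )
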