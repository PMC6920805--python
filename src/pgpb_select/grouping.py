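"""Stage 1 diagnostics — phenotype pattern groups and PCA.

Isolates sharing the same binary response vector over the four screening
traits form a homogeneous phenotype group (at most 2^4 = 16 groups).
Grouping is exact-pattern identity, not distance-based. A PCA on the
standardized binary matrix exposes the leading traits and the variance
each component explains; it is a diagnostic view only — no selection
decision depends on PCA coordinates.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .records import QualitativeTrait
from .screen import BinaryTraitMatrix


@dataclass
class PhenotypeGroup:
    """Isolates sharing one exact binary response pattern."""

    pattern: tuple[int, ...]
    label: str
    members: list[str]
    positive_to_all: bool = False
    negative_to_all: bool = False


@dataclass
class PcaResult:
    """PCA of the standardized binary trait matrix.

    ``loadings`` holds trait-component correlation coefficients; on
    standardized data their magnitude is at most 1. ``variance_fraction``
    is each component's share of the total variance (all components sum
    to 1). Traits with zero variance are dropped before the analysis and
    reported in ``excluded_traits``.
    """

    loadings: pd.DataFrame  # traits x components
    variance_fraction: np.ndarray
    scores: np.ndarray  # isolates x components
    excluded_traits: list[QualitativeTrait] = field(default_factory=list)


def pattern_groups(matrix: BinaryTraitMatrix) -> list[PhenotypeGroup]:
    """Partition isolates into exact-pattern groups.

    Labels are assigned A, B, C, ... in descending lexicographic order of
    pattern, so they are reproducible from the data alone. The all-ones and
    all-zeros patterns are flagged positive-to-all / negative-to-all.
    """
    if len(matrix.isolates) == 0:
        raise ValueError("empty matrix")
    by_pattern: dict[tuple[int, ...], list[str]] = {}
    for iso, row in zip(matrix.isolates, matrix.entries):
        by_pattern.setdefault(tuple(int(v) for v in row), []).append(iso)

    n_traits = len(matrix.traits)
    groups = []
    for label, pattern in zip(
        string.ascii_uppercase, sorted(by_pattern, reverse=True)
    ):
        groups.append(
            PhenotypeGroup(
                pattern=pattern,
                label=label,
                members=sorted(by_pattern[pattern]),
                positive_to_all=pattern == (1,) * n_traits,
                negative_to_all=pattern == (0,) * n_traits,
            )
        )
    return groups


def run_pca(matrix: BinaryTraitMatrix, n_components: int | None = None) -> PcaResult:
    """PCA on the standardized (correlation-matrix) binary trait data.

    Components are ordered by decreasing explained variance and the sign of
    each is fixed so that its largest-magnitude loading is positive.
    Zero-variance traits are excluded with a warning; if every trait has
    zero variance the analysis is impossible.
    """
    X = matrix.entries.astype(float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 isolates")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    excluded = [t for t, k in zip(matrix.traits, keep) if not k]
    if excluded:
        warnings.warn(
            "zero-variance traits excluded from PCA: "
            + ", ".join(t.value for t in excluded),
            stacklevel=2,
        )
    if keep.sum() < 2:
        raise ValueError("PCA needs at least 2 traits with nonzero variance")
    kept_traits = [t for t, k in zip(matrix.traits, keep) if k]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    max_rank = min(Z.shape[0] - 1, Z.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z)

    # On standardized data, eigvec * sqrt(eigval) is the trait-score correlation.
    loadings = pca.components_.T * np.sqrt(pca.explained_variance_)
    # Deterministic sign: largest-magnitude loading of each component positive.
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0

    return PcaResult(
        loadings=pd.DataFrame(
            loadings,
            index=pd.Index([t.value for t in kept_traits], name="trait"),
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        variance_fraction=pca.explained_variance_ratio_.copy(),
        scores=scores,
        excluded_traits=excluded,
    )
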