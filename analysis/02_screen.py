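#!/usr/bin/env python
"""Stage 1: binary coding, positivity summary, phenotype groups, PCA.

Reads results/data/, collapses the qualitative replicates to 0/1 codes,
summarizes per-group positivity, partitions isolates into exact-pattern
phenotype groups, and runs the diagnostic PCA. Writes binary_matrix.csv,
positivity.csv, phenotype_groups.csv, pca_loadings.csv under results/.
"""

from pathlib import Path

import pandas as pd

from pgpb_select import build_matrix, io, run_pca, summarize_positivity
from pgpb_select.grouping import pattern_groups
from pgpb_select.screen import positivity_frame

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = io.read_dataset(ROOT / "data")
    matrix = build_matrix(records.values())
    matrix.to_frame().to_csv(ROOT / "binary_matrix.csv")

    groups_map = {r.isolate_id: r.group for r in records.values()}
    pos = positivity_frame(summarize_positivity(matrix, groups_map))
    pos.to_csv(ROOT / "positivity.csv", index=False)

    phen = pattern_groups(matrix)
    pd.DataFrame(
        {
            "label": [g.label for g in phen],
            "pattern": ["".join(map(str, g.pattern)) for g in phen],
            "n_members": [len(g.members) for g in phen],
            "members": [";".join(g.members) for g in phen],
            "positive_to_all": [g.positive_to_all for g in phen],
            "negative_to_all": [g.negative_to_all for g in phen],
        }
    ).to_csv(ROOT / "phenotype_groups.csv", index=False)

    pca = run_pca(matrix, n_components=2)
    pca.loadings.to_csv(ROOT / "pca_loadings.csv")

    print(f"{len(records)} isolates, {len(phen)} phenotype patterns")
    pos_all = [g for g in phen if g.positive_to_all]
    neg_all = [g for g in phen if g.negative_to_all]
    if pos_all:
        print(f"positive-to-all group: {len(pos_all[0].members)} isolates")
    if neg_all:
        print(f"negative-to-all group: {len(neg_all[0].members)} isolates")
    print(
        "first two components explain "
        f"{100 * pca.variance_fraction.sum():.0f}% of the total variance"
    )


if __name__ == "__main__":
    main()
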