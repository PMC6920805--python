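#!/usr/bin/env python
"""Stage 2c: the multi-round selection.

Reads results/data/, runs the full second-stage pipeline (QC, quartile
coding, first-round code-3 + top-Tukey-letter rule at alpha=0.05,
second-round >= 2-trait rule, viability exclusion) and writes
selection_report.csv under results/.
"""

from pathlib import Path

from pgpb_select import io, run_selection

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = list(io.read_dataset(ROOT / "data").values())
    report, codes, summaries, qc_log = run_selection(records)
    io.write_report(report, ROOT / "selection_report.csv")

    first_ids = sorted({i for i, _, _ in report.first_round})
    print(f"first round: {len(first_ids)} isolates "
          f"({len(report.first_round)} group x parameter wins)")
    print(f"second round: {len(report.second_round)} isolates with >= 2 traits")
    print(f"excluded for viability: {len(report.excluded)}")
    print(f"final candidates: {len(report.final)}")
    print("top of the list:", ", ".join(report.final[:10]))


if __name__ == "__main__":
    main()
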