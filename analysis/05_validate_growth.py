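#!/usr/bin/env python
"""Stage 3: growth-chamber validation of selected candidates.

Takes the first eight finally selected isolates from results/
selection_report.csv as growth-chamber treatments, simulates pot-level
biomass and height with +50%/+25% effects for half of them (the others
null), and analyzes the pots with one-way ANOVA + Tukey at alpha=0.01.
Writes growth.csv and validation.csv under results/.
"""

import argparse
from pathlib import Path

from pgpb_select import GeneratorConfig, generate_growth, io, validate
from pgpb_select.growth import validation_frame

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    report = io.read_report(ROOT / "selection_report.csv")
    treatments = report.final[:8]
    if not treatments:
        raise SystemExit("no selected isolates; run 04_select.py first")
    effects = {
        t: ((1.5, 1.25) if i % 2 == 0 else (1.0, 1.0))
        for i, t in enumerate(treatments)
    }
    cfg = GeneratorConfig(seed=args.seed, growth_effects=effects)
    pots = generate_growth(cfg)
    io.write_growth(pots, ROOT / "growth.csv")

    results = validate(pots, alpha=0.01)
    frame = validation_frame(results)
    frame.to_csv(ROOT / "validation.csv", index=False)

    print(frame.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    control_letters = set(
        next(r for r in results if r.treatment == "control").letters_biomass
    )
    distinct = [
        r.treatment
        for r in results
        if r.treatment != "control"
        and not set(r.letters_biomass) & control_letters
    ]
    print("treatments with biomass significantly above control (p<0.01):",
          ", ".join(distinct) or "none")


if __name__ == "__main__":
    main()
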