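"""Stage 3 — growth-chamber validation statistics.

Candidate strains are inoculated on durum wheat seeds grown in pots; dry
biomass (g/pot) and aerial height (cm) at tillering are compared to an
uninoculated control. Each response is analyzed independently with a
one-way ANOVA and Tukey HSD at alpha = 0.01, and treatment effects are
reported as percent change of the treatment mean relative to the control
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .records import CONTROL_TREATMENT, GrowthRecord
from .stats import tukey_letters


def percent_change(treatment_mean: float, control_mean: float) -> float:
    """100 * (treatment - control) / control; control mean must be positive."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (treatment_mean - control_mean) / control_mean


@dataclass
class ValidationResult:
    """Per-treatment growth-chamber summary with Tukey letters."""

    treatment: str
    mean_biomass: float
    mean_height: float
    pct_biomass_change: float
    pct_height_change: float
    letters_biomass: str
    letters_height: str
    n_pots: int


def validate(
    growth: Iterable[GrowthRecord], alpha: float = 0.01
) -> list[ValidationResult]:
    """Treatment means, percent changes vs control, and Tukey letters.

    Requires a ``control`` treatment and >= 2 pots per treatment. The
    control row is listed first; treatments follow in descending biomass
    order.
    """
    biomass: dict[str, list[float]] = {}
    height: dict[str, list[float]] = {}
    for rec in growth:
        biomass.setdefault(rec.treatment, []).append(rec.biomass_dry_matter)
        height.setdefault(rec.treatment, []).append(rec.height)
    if CONTROL_TREATMENT not in biomass:
        raise ValueError("growth data must contain a 'control' treatment")
    for trt, vals in biomass.items():
        if len(vals) < 2:
            raise ValueError(f"treatment {trt!r} has fewer than 2 pots")

    letters_b = tukey_letters(biomass, alpha=alpha)
    letters_h = tukey_letters(height, alpha=alpha)
    control_b = float(np.mean(biomass[CONTROL_TREATMENT]))
    control_h = float(np.mean(height[CONTROL_TREATMENT]))

    order = [CONTROL_TREATMENT] + [
        t for t in letters_b.levels if t != CONTROL_TREATMENT
    ]
    return [
        ValidationResult(
            treatment=trt,
            mean_biomass=float(np.mean(biomass[trt])),
            mean_height=float(np.mean(height[trt])),
            pct_biomass_change=percent_change(float(np.mean(biomass[trt])), control_b),
            pct_height_change=percent_change(float(np.mean(height[trt])), control_h),
            letters_biomass=letters_b.letters[trt],
            letters_height=letters_h.letters[trt],
            n_pots=len(biomass[trt]),
        )
        for trt in order
    ]


def validation_frame(results: list[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "treatment": [r.treatment for r in results],
            "n_pots": [r.n_pots for r in results],
            "mean_biomass_g": [r.mean_biomass for r in results],
            "pct_biomass_change": [r.pct_biomass_change for r in results],
            "letters_biomass": [r.letters_biomass for r in results],
            "mean_height_cm": [r.mean_height for r in results],
            "pct_height_change": [r.pct_height_change for r in results],
            "letters_height": [r.letters_height for r in results],
        }
    )
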