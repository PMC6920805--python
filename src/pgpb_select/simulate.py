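"""Synthetic screening and growth-chamber data with the campaign's structure.

The generator emulates the statistical shape the pipeline assumes so every
stage is testable without the (unpublished) raw data:

* four functional groups at the campaign's isolate counts, with per-group
  qualitative positivity at the published rates;
* quantitative traits drawn from a zero-inflated lognormal whose positive
  part is calibrated so its median and upper quartile equal the published
  population summaries — the published quartile table shows a first
  quartile of 0 for one group x parameter, i.e. a point mass of
  assay-negative isolates, and a lognormal positive part is the standard
  model for strictly positive assay concentrations;
* triplicate measurement noise at a configurable CV with occasional gross
  outliers (one replicate multiplied by a factor >= 2) to exercise the
  Dixon gate;
* quantitative assays gated on the qualitative screen as in the campaign
  (P-mineralization only for P-solubilization-positive isolates,
  quantitative nitrification only for screen-nitrification-positive ones,
  IAA for everyone);
* optional planted "elite" strains — best-in-class performers whose trait
  value sits a fixed margin above the group's natural maximum — and
  growth-chamber responses with multiplicative treatment effects
  (defaults +50% biomass, +25% height for elites).

A single integer seed drives a hierarchical stream (one child stream per
isolate, keyed by group and index), so enlarging one group never perturbs
the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .records import (
    GROUP_ORDER,
    PARAMETER_ORDER,
    TRAIT_ORDER,
    CONTROL_TREATMENT,
    FunctionalGroup,
    GrowthRecord,
    IsolateRecord,
    QualitativeTrait,
    QuantParameter,
)

#: Standard normal upper-quartile point, used to invert lognormal quantiles.
Z_75 = 0.6744897501960817


@dataclass(frozen=True)
class CalibratedDistribution:
    """Zero-inflated lognormal for one group x parameter.

    ``zero_mass`` is the probability of a structural zero (assay-negative
    isolate); the positive part is lognormal with median
    ``exp(log_location)`` and log-scale ``log_scale``.
    """

    zero_mass: float
    log_location: float
    log_scale: float

    def __post_init__(self) -> None:
        if not 0 <= self.zero_mass < 1:
            raise ValueError("zero_mass must be in [0, 1)")
        if self.log_scale <= 0:
            raise ValueError("log_scale must be positive")

    @property
    def median(self) -> float:
        return math.exp(self.log_location)

    @property
    def q3(self) -> float:
        return math.exp(self.log_location + Z_75 * self.log_scale)


def calibrate_lognormal(
    median: float, q3: float, zero_mass: float = 0.0
) -> CalibratedDistribution:
    """Lognormal whose positive part has the given median and upper quartile.

    Closed-form inversion: log_location = ln(median) and
    log_scale = ln(q3 / median) / z_0.75 with z_0.75 ~ 0.6745.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if q3 <= median:
        raise ValueError("q3 must exceed the median (degenerate dispersion)")
    return CalibratedDistribution(
        zero_mass=zero_mass,
        log_location=math.log(median),
        log_scale=math.log(q3 / median) / Z_75,
    )


def _default_calibration() -> dict[tuple[FunctionalGroup, QuantParameter], CalibratedDistribution]:
    """Published quartile table as calibrated distributions.

    The internally inconsistent pseudomonad P-mineralization row cannot be
    inverted; for that cell the published median is kept, the upper
    quartile is set at twice the median, and the zero mass is raised to
    0.3 (its printed first quartile of 0 implies at least a quarter of
    assay-negative isolates). Every other cell uses a 0.1 zero mass —
    its printed first quartile is positive, so the zero mass is below
    0.25 and otherwise unreported.
    """
    calib = {}
    for (group, param), (_q1, med, q3) in reference._QUARTILE_ROWS.items():
        if (group, param) in reference.INVALID_QUARTILE_ROWS:
            calib[(group, param)] = calibrate_lognormal(med, 2.0 * med, zero_mass=0.3)
        else:
            calib[(group, param)] = calibrate_lognormal(med, q3, zero_mass=0.1)
    return calib


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic campaign.

    Defaults reproduce the published screening conditions: group sizes,
    per-group qualitative positivity, and quantitative calibrations from
    the published quartile table. ``replicate_cv`` (within-isolate
    multiplicative noise, as a fraction) defaults to 0.05 so that clean
    triplets pass the 10% CV gate; ``outlier_rate`` triplets receive one
    gross outlier. Growth-chamber pots use multiplicative effects per
    treatment over control means of 2.0 g biomass and 30.0 cm height
    (tillering-stage scale) with 10% pot-level CV.
    """

    seed: int = 0
    n_per_group: dict[FunctionalGroup, int] = field(
        default_factory=lambda: dict(reference.GROUP_SIZES)
    )
    positivity: dict[tuple[FunctionalGroup, QualitativeTrait], float] = field(
        default_factory=lambda: dict(reference.POSITIVITY)
    )
    quant_calibration: dict[
        tuple[FunctionalGroup, QuantParameter], CalibratedDistribution
    ] = field(default_factory=_default_calibration)
    n_replicates: int = 3
    replicate_cv: float = 0.05
    replicate_flip_rate: float = 0.0
    outlier_rate: float = 0.05
    outlier_factor_range: tuple[float, float] = (2.0, 5.0)
    gate_quant_on_screen: bool = True
    n_elites_per_group: int = 0
    elite_margin: float = 1.5
    growth_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    control_biomass: float = 2.0
    control_height: float = 30.0
    growth_cv: float = 0.10
    n_pots: int = 3

    def __post_init__(self) -> None:
        for p in self.positivity.values():
            if not 0 <= p <= 1:
                raise ValueError("positivity probabilities must be in [0, 1]")
        for n in self.n_per_group.values():
            if n < 0:
                raise ValueError("group sizes must be non-negative")
        if not 0 <= self.outlier_rate <= 1 or not 0 <= self.replicate_flip_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        for bm, h in self.growth_effects.values():
            if bm <= 0 or h <= 0:
                raise ValueError("growth multipliers must be positive")


@dataclass
class SyntheticDataset:
    """Generated campaign: records, growth pots, elite log, latent values."""

    records: list[IsolateRecord]
    growth: list[GrowthRecord]
    elites: list[tuple[str, QuantParameter]]
    latent: pd.DataFrame  # isolate x parameter true values (NaN = assay-negative)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


#: Qualitative trait gating each quantitative assay (IAA is ungated).
_GATE_TRAIT: dict[QuantParameter, QualitativeTrait] = {
    QuantParameter.P_MINERALIZATION: QualitativeTrait.P_SOLUBILIZATION,
    QuantParameter.NITRIFICATION: QualitativeTrait.NITRIFICATION_QUAL,
}


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a full synthetic campaign; deterministic given the seed.

    Elite strains (``n_elites_per_group`` > 0) are the last isolates of
    each group; each is elite for one parameter (cycling through the
    parameter order). An elite is a best-in-class performer: its positive
    value is ``elite_margin`` times the largest natural value drawn for
    that group x parameter (falling back to four times the calibrated
    upper quartile when no natural value exists), and its gating
    qualitative trait is forced positive so the assay is performed.
    """
    records: list[IsolateRecord] = []
    elites: list[tuple[str, QuantParameter]] = []
    latent_rows: dict[str, dict[str, float]] = {}

    for g_idx, group in enumerate(GROUP_ORDER):
        n = config.n_per_group.get(group, 0)
        n_elites = min(config.n_elites_per_group, n)
        n_natural = n - n_elites

        # Phase 1: natural draws for every isolate (elites force their
        # gating trait positive so the planted assay is performed).
        group_records: list[IsolateRecord] = []
        group_max: dict[QuantParameter, float] = {}
        elite_params: dict[str, QuantParameter] = {}
        for i in range(n):
            elite_param = (
                PARAMETER_ORDER[(i - n_natural) % len(PARAMETER_ORDER)]
                if i >= n_natural
                else None
            )
            rec, lat = _draw_isolate(config, group, g_idx, i, elite_param=elite_param)
            if elite_param is not None:
                elite_params[rec.isolate_id] = elite_param
            group_records.append(rec)
            latent_rows[rec.isolate_id] = lat
            for param in PARAMETER_ORDER:
                v = lat.get(param.value)
                if v is not None and not math.isnan(v):
                    group_max[param] = max(group_max.get(param, 0.0), v)

        # Phase 2: plant each elite a fixed margin above the cell maximum.
        for i, rec in enumerate(group_records):
            param = elite_params.get(rec.isolate_id)
            if param is None:
                continue
            dist = config.quant_calibration.get((group, param))
            if dist is None:
                raise ValueError(
                    f"cannot plant an elite for uncalibrated "
                    f"{group.value}/{param.value}"
                )
            base = group_max.get(param, 4.0 * dist.q3)
            value = config.elite_margin * base
            rng = _rng(config.seed, g_idx, i, 1)
            sigma_rep = math.sqrt(math.log(1.0 + config.replicate_cv**2))
            rec.quant[param] = [
                value * math.exp(rng.normal(0.0, sigma_rep))
                for _ in range(config.n_replicates)
            ]
            latent_rows[rec.isolate_id][param.value] = value
            elites.append((rec.isolate_id, param))
        records.extend(group_records)

    growth = generate_growth(config) if config.growth_effects else []
    latent = pd.DataFrame.from_dict(latent_rows, orient="index")
    latent.index.name = "isolate_id"
    return SyntheticDataset(records=records, growth=growth, elites=elites, latent=latent)


def _draw_isolate(
    config: GeneratorConfig,
    group: FunctionalGroup,
    g_idx: int,
    i: int,
    elite_param: QuantParameter | None,
) -> tuple[IsolateRecord, dict[str, float]]:
    sigma_rep = math.sqrt(math.log(1.0 + config.replicate_cv**2))
    iso_id = f"{i + 1}{group.suffix}"
    rng = _rng(config.seed, g_idx, i)

    phenotype: dict[QualitativeTrait, list[bool]] = {}
    latent_positive: dict[QualitativeTrait, bool] = {}
    gate_trait = _GATE_TRAIT.get(elite_param) if elite_param is not None else None
    for trait in TRAIT_ORDER:
        p = config.positivity.get((group, trait))
        if p is None:
            continue
        latent_pos = bool(rng.random() < p) or trait == gate_trait
        latent_positive[trait] = latent_pos
        outcomes = []
        for _ in range(config.n_replicates):
            flip = rng.random() < config.replicate_flip_rate
            outcomes.append(latent_pos != flip)
        phenotype[trait] = outcomes

    quant: dict[QuantParameter, list[float]] = {}
    lat: dict[str, float] = {}
    for param in PARAMETER_ORDER:
        dist = config.quant_calibration.get((group, param))
        if dist is None:
            continue
        # The campaign only ran gated assays on screen-positive isolates.
        gated_out = (
            config.gate_quant_on_screen
            and param in _GATE_TRAIT
            and not latent_positive.get(_GATE_TRAIT[param], False)
        )
        if param == elite_param:
            # Placeholder natural draw; overwritten with the planted value.
            true = math.exp(rng.normal(dist.log_location, dist.log_scale))
        elif gated_out:
            continue  # assay not performed: absent, not zero
        elif rng.random() < dist.zero_mass:
            lat[param.value] = float("nan")
            continue  # assay-negative: no quantifiable value
        else:
            true = math.exp(rng.normal(dist.log_location, dist.log_scale))
        lat[param.value] = true
        reps = [
            true * math.exp(rng.normal(0.0, sigma_rep))
            for _ in range(config.n_replicates)
        ]
        if config.n_replicates >= 3 and rng.random() < config.outlier_rate:
            j = int(rng.integers(config.n_replicates))
            reps[j] *= rng.uniform(*config.outlier_factor_range)
        quant[param] = reps

    return (
        IsolateRecord(isolate_id=iso_id, group=group, phenotype=phenotype, quant=quant),
        lat,
    )


def generate_growth(config: GeneratorConfig) -> list[GrowthRecord]:
    """Growth-chamber pots: control plus one treatment per configured effect."""
    sigma = math.sqrt(math.log(1.0 + config.growth_cv**2))
    pots: list[GrowthRecord] = []
    treatments = [(CONTROL_TREATMENT, (1.0, 1.0))] + sorted(config.growth_effects.items())
    for t_idx, (name, (bm_mult, h_mult)) in enumerate(treatments):
        rng = _rng(config.seed, 10_000, t_idx)
        for pot in range(config.n_pots):
            pots.append(
                GrowthRecord(
                    pot_id=f"{name}-{pot + 1}",
                    treatment=name,
                    biomass_dry_matter=config.control_biomass
                    * bm_mult
                    * math.exp(rng.normal(0.0, sigma)),
                    height=config.control_height
                    * h_mult
                    * math.exp(rng.normal(0.0, sigma)),
                )
            )
    return pots


def elite_growth_config(
    config: GeneratorConfig,
    treatments: list[str],
    biomass_multiplier: float = 1.5,
    height_multiplier: float = 1.25,
) -> GeneratorConfig:
    """Copy of ``config`` with the given treatments at the default elite effects."""
    return replace(
        config,
        growth_effects={
            t: (biomass_multiplier, height_multiplier) for t in treatments
        },
    )
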