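"""Synthetic-data generator: calibration, determinism, recovery properties."""

import math

import numpy as np
import pytest

from pgpb_select import io
from pgpb_select.coding import summaries_from_records
from pgpb_select.records import FunctionalGroup, QualitativeTrait, QuantParameter
from pgpb_select.simulate import (
    Z_75,
    GeneratorConfig,
    calibrate_lognormal,
    generate_dataset,
)

_M = FunctionalGroup.MESOPHILIC


def test_calibrate_lognormal_closed_form():
    # published mesophilic IAA summaries: median 18.86, q3 38.91
    d = calibrate_lognormal(18.86, 38.91)
    assert d.log_scale == pytest.approx(math.log(38.91 / 18.86) / 0.6745, rel=1e-3)
    assert d.median == pytest.approx(18.86)
    assert d.q3 == pytest.approx(38.91)
    # symmetric check: inputs (1, e^z75) -> unit log-scale
    assert calibrate_lognormal(1.0, math.exp(Z_75)).log_scale == pytest.approx(1.0)


def test_calibrate_lognormal_degenerate_errors():
    with pytest.raises(ValueError):
        calibrate_lognormal(2.0, 2.0)
    with pytest.raises(ValueError):
        calibrate_lognormal(0.0, 1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(positivity={(_M, QualitativeTrait.AMMONIUM): 1.2})
    with pytest.raises(ValueError):
        GeneratorConfig(outlier_rate=-0.1)
    with pytest.raises(ValueError):
        GeneratorConfig(growth_effects={"1M": (0.0, 1.0)})


def test_same_seed_reproduces_dataset_bytes(tmp_path):
    cfg = GeneratorConfig(
        seed=3,
        n_per_group={g: 15 for g in FunctionalGroup},
        growth_effects={"1M": (1.5, 1.25)},
    )
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        ds = generate_dataset(cfg)
        io.write_dataset(ds.records, d, growth=ds.growth)
    for fname in (
        io.ISOLATES_FILE,
        io.QUALITATIVE_FILE,
        io.QUANTITATIVE_FILE,
        io.GROWTH_FILE,
    ):
        assert (d1 / fname).read_bytes() == (d2 / fname).read_bytes()


def test_adding_isolates_does_not_perturb_earlier_draws():
    small = GeneratorConfig(seed=9, n_per_group={g: 10 for g in FunctionalGroup})
    large = GeneratorConfig(seed=9, n_per_group={g: 20 for g in FunctionalGroup})
    ds_small = generate_dataset(small)
    ds_large = generate_dataset(large)
    by_id = {r.isolate_id: r for r in ds_large.records}
    for rec in ds_small.records:
        assert by_id[rec.isolate_id] == rec


def test_generated_dataset_round_trips_through_io(tmp_path, small_campaign):
    """Pipeline closure: generated data passes read_dataset validation."""
    io.write_dataset(small_campaign.records, tmp_path, growth=small_campaign.growth)
    back = io.read_dataset(tmp_path)
    assert back == {r.isolate_id: r for r in small_campaign.records}


def test_quantile_recovery_at_large_n():
    """Positive-part sample median/q3 match the calibration within 3 SE."""
    n = 10_000
    cfg = GeneratorConfig(
        seed=2,
        n_per_group={
            _M: n,
            FunctionalGroup.SPORE_FORMING: 0,
            FunctionalGroup.PSEUDOMONADS: 0,
            FunctionalGroup.ACTINOBACTERIA: 0,
        },
    )
    ds = generate_dataset(cfg)
    for param, (target_med, target_q3) in {
        QuantParameter.IAA: (18.86, 38.91),
        QuantParameter.P_MINERALIZATION: (1.81, 2.61),
    }.items():
        values = ds.latent[param.value].dropna().to_numpy()
        dist = cfg.quant_calibration[(_M, param)]
        for prob, target in ((0.5, target_med), (0.75, target_q3)):
            observed = np.quantile(values, prob)
            # order-statistic SE: sqrt(p(1-p)/n) / f(quantile)
            z = (math.log(target) - dist.log_location) / dist.log_scale
            density = math.exp(-z * z / 2) / (
                target * dist.log_scale * math.sqrt(2 * math.pi)
            )
            se = math.sqrt(prob * (1 - prob) / values.size) / density
            assert abs(observed - target) <= 3 * se, (param, prob)


def test_zero_mass_and_gating_produce_absent_assays(small_campaign):
    """Structural zeros and screen-gating leave assays absent, never 0.0."""
    n_missing = sum(
        1 for r in small_campaign.records if QuantParameter.P_MINERALIZATION not in r.quant
    )
    assert n_missing > 0
    for rec in small_campaign.records:
        for values in rec.quant.values():
            assert all(v > 0 for v in values)


def test_outlier_injection_rate():
    """~outlier_rate of triplets contain one gross outlier (ratio >= ~2)."""
    cfg = GeneratorConfig(
        seed=21,
        n_per_group={_M: 2000, FunctionalGroup.SPORE_FORMING: 0,
                     FunctionalGroup.PSEUDOMONADS: 0, FunctionalGroup.ACTINOBACTERIA: 0},
        outlier_rate=0.10,
        gate_quant_on_screen=False,
    )
    ds = generate_dataset(cfg)
    n_sets, n_outliers = 0, 0
    for rec in ds.records:
        for values in rec.quant.values():
            n_sets += 1
            if max(values) / np.median(values) > 1.8:
                n_outliers += 1
    rate = n_outliers / n_sets
    assert rate == pytest.approx(0.10, abs=0.02)


def test_quartile_summaries_of_generated_data_near_calibration():
    """End-to-end: pooled-replicate quartiles land near the calibrated pair."""
    cfg = GeneratorConfig(
        seed=4,
        n_per_group={g: 400 for g in FunctionalGroup},
        gate_quant_on_screen=False,
        outlier_rate=0.0,
    )
    ds = generate_dataset(cfg)
    summaries = summaries_from_records(ds.records)
    for (group, param), s in summaries.items():
        dist = cfg.quant_calibration[(group, param)]
        # zero-inflation shifts pooled quantiles up: compare positive part only
        values = np.concatenate(
            [r.quant[param] for r in ds.records if r.group == group and param in r.quant]
        )
        # order-statistic 3-SE band at the (conservative) isolate count
        n_eff = sum(1 for r in ds.records if r.group == group and param in r.quant)
        density = 1.0 / (dist.median * dist.log_scale * math.sqrt(2 * math.pi))
        se = math.sqrt(0.25 / n_eff) / density
        assert abs(np.median(values) - dist.median) <= 3 * se, (group, param)
        assert s.q1 <= s.median <= s.q3
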