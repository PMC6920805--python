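"""Readers and writers for the pipeline's delimited-text formats.

All files are comma-delimited UTF-8 with a mandatory header row and "." as
the decimal mark. The screening dataset is split over three long-format
("tidy") files plus one growth-chamber file:

``isolates.csv``
    isolate_id, group, viability_ok
``qualitative.csv``
    isolate_id, trait, replicate, outcome (pos/neg)
``quantitative.csv``
    isolate_id, parameter, replicate, value
``growth.csv``
    pot_id, treatment, biomass_g, height_cm

One row per measurement: replicate counts may differ between assays, so a
wide table would be ragged. Reading is order-independent — rows are keyed
by isolate and sorted by replicate index — and a written dataset re-reads
to an equal one.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .records import (
    FunctionalGroup,
    GrowthRecord,
    IsolateRecord,
    QualitativeTrait,
    QuantParameter,
)
from .selection import SelectionReport

ISOLATES_FILE = "isolates.csv"
QUALITATIVE_FILE = "qualitative.csv"
QUANTITATIVE_FILE = "quantitative.csv"
GROWTH_FILE = "growth.csv"

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}
_POSITIVE = {"pos", "positive", "+", "1", "true"}
_NEGATIVE = {"neg", "negative", "-", "0", "false"}


def _parse_bool(raw: str, *, where: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse boolean {raw!r}")


def _parse_outcome(raw: str, *, where: str) -> bool:
    s = str(raw).strip().lower()
    if s in _POSITIVE:
        return True
    if s in _NEGATIVE:
        return False
    raise ValueError(f"{where}: cannot parse outcome {raw!r} (expected pos/neg)")


def read_dataset(directory: str | os.PathLike) -> dict[str, IsolateRecord]:
    """Read a screening dataset from a directory of the standard CSV files.

    Returns an isolate_id -> IsolateRecord mapping sorted by isolate id.
    Duplicate ids, a group inconsistent with the id suffix, and negative
    assay values are hard errors. Assays with no rows for an isolate are
    left absent from the record.
    """
    directory = Path(directory)
    iso = pd.read_csv(directory / ISOLATES_FILE, dtype=str)
    _require_columns(iso, ["isolate_id", "group", "viability_ok"], ISOLATES_FILE)
    if iso["isolate_id"].duplicated().any():
        dupes = sorted(iso.loc[iso["isolate_id"].duplicated(), "isolate_id"])
        raise ValueError(f"{ISOLATES_FILE}: duplicate isolate ids {dupes}")

    records: dict[str, IsolateRecord] = {}
    for row in iso.itertuples(index=False):
        try:
            group = FunctionalGroup(row.group)
        except ValueError:
            raise ValueError(
                f"{ISOLATES_FILE}: unknown group {row.group!r} for isolate "
                f"{row.isolate_id!r}"
            ) from None
        records[row.isolate_id] = IsolateRecord(
            isolate_id=row.isolate_id,
            group=group,
            viability_ok=_parse_bool(
                row.viability_ok, where=f"{ISOLATES_FILE} isolate {row.isolate_id}"
            ),
        )

    qual_path = directory / QUALITATIVE_FILE
    if qual_path.exists():
        qual = pd.read_csv(qual_path, dtype=str)
        _require_columns(
            qual, ["isolate_id", "trait", "replicate", "outcome"], QUALITATIVE_FILE
        )
        qual = qual.assign(replicate=qual["replicate"].astype(int))
        for (iso_id, trait_name), chunk in qual.groupby(
            ["isolate_id", "trait"], sort=True
        ):
            rec = _lookup(records, iso_id, QUALITATIVE_FILE)
            trait = QualitativeTrait(trait_name)
            chunk = chunk.sort_values("replicate")
            rec.phenotype[trait] = [
                _parse_outcome(o, where=f"{QUALITATIVE_FILE} isolate {iso_id}")
                for o in chunk["outcome"]
            ]

    quant_path = directory / QUANTITATIVE_FILE
    if quant_path.exists():
        quant = pd.read_csv(quant_path, dtype=str)
        _require_columns(
            quant, ["isolate_id", "parameter", "replicate", "value"], QUANTITATIVE_FILE
        )
        quant = quant.assign(
            replicate=quant["replicate"].astype(int),
            value=quant["value"].astype(float),
        )
        if (quant["value"] < 0).any():
            bad = quant.loc[quant["value"] < 0].iloc[0]
            raise ValueError(
                f"{QUANTITATIVE_FILE}: negative value {bad.value} for isolate "
                f"{bad.isolate_id!r}, parameter {bad.parameter!r}"
            )
        for (iso_id, param_name), chunk in quant.groupby(
            ["isolate_id", "parameter"], sort=True
        ):
            rec = _lookup(records, iso_id, QUANTITATIVE_FILE)
            param = QuantParameter(param_name)
            chunk = chunk.sort_values("replicate")
            rec.quant[param] = [float(v) for v in chunk["value"]]

    # Re-validate after filling replicate lists (suffix checked at construction).
    for rec in records.values():
        rec.__post_init__()
    return dict(sorted(records.items()))


def _lookup(records: dict[str, IsolateRecord], iso_id: str, fname: str) -> IsolateRecord:
    if iso_id not in records:
        raise ValueError(f"{fname}: isolate {iso_id!r} not declared in {ISOLATES_FILE}")
    return records[iso_id]


def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{fname}: missing columns {missing}")


def read_growth(path: str | os.PathLike) -> list[GrowthRecord]:
    """Read growth-chamber pot measurements from ``growth.csv``."""
    df = pd.read_csv(path)
    _require_columns(df, ["pot_id", "treatment", "biomass_g", "height_cm"], GROWTH_FILE)
    return [
        GrowthRecord(
            pot_id=str(r.pot_id),
            treatment=str(r.treatment),
            biomass_dry_matter=float(r.biomass_g),
            height=float(r.height_cm),
        )
        for r in df.itertuples(index=False)
    ]


def write_dataset(
    records: dict[str, IsolateRecord] | list[IsolateRecord],
    directory: str | os.PathLike,
    growth: list[GrowthRecord] | None = None,
) -> None:
    """Write a screening dataset (and optionally growth data) to a directory."""
    if isinstance(records, dict):
        records = list(records.values())
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {
            "isolate_id": [r.isolate_id for r in records],
            "group": [r.group.value for r in records],
            "viability_ok": [r.viability_ok for r in records],
        }
    ).to_csv(directory / ISOLATES_FILE, index=False)

    qual_rows = [
        (r.isolate_id, trait.value, i + 1, "pos" if o else "neg")
        for r in records
        for trait, outcomes in r.phenotype.items()
        for i, o in enumerate(outcomes)
    ]
    pd.DataFrame(
        qual_rows, columns=["isolate_id", "trait", "replicate", "outcome"]
    ).to_csv(directory / QUALITATIVE_FILE, index=False)

    quant_rows = [
        (r.isolate_id, param.value, i + 1, repr(v))
        for r in records
        for param, values in r.quant.items()
        for i, v in enumerate(values)
    ]
    pd.DataFrame(
        quant_rows, columns=["isolate_id", "parameter", "replicate", "value"]
    ).to_csv(directory / QUANTITATIVE_FILE, index=False)

    if growth is not None:
        write_growth(growth, directory / GROWTH_FILE)


def write_growth(growth: list[GrowthRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "pot_id": [g.pot_id for g in growth],
            "treatment": [g.treatment for g in growth],
            "biomass_g": [g.biomass_dry_matter for g in growth],
            "height_cm": [g.height for g in growth],
        }
    ).to_csv(path, index=False)


def write_report(report: SelectionReport, path: str | os.PathLike) -> None:
    """Serialize a selection report to a single long-format CSV.

    Columns: section (first_round / second_round / excluded / final),
    isolate_id, parameter (first-round rows only), detail (rule or reason).
    ``read_report`` reconstructs an equal report.
    """
    rows: list[tuple[str, str, str, str]] = []
    for iso_id, param, rule in report.first_round:
        rows.append(("first_round", iso_id, param.value, rule))
    for iso_id, rule in report.second_round:
        rows.append(("second_round", iso_id, "", rule))
    for iso_id, reason in report.excluded:
        rows.append(("excluded", iso_id, "", reason))
    for iso_id in report.final:
        rows.append(("final", iso_id, "", ""))
    pd.DataFrame(rows, columns=["section", "isolate_id", "parameter", "detail"]).to_csv(
        path, index=False
    )


def read_report(path: str | os.PathLike) -> SelectionReport:
    """Read back a selection report written by :func:`write_report`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["section", "isolate_id", "parameter", "detail"], str(path))
    report = SelectionReport()
    for r in df.itertuples(index=False):
        if r.section == "first_round":
            report.first_round.append((r.isolate_id, QuantParameter(r.parameter), r.detail))
        elif r.section == "second_round":
            report.second_round.append((r.isolate_id, r.detail))
        elif r.section == "excluded":
            report.excluded.append((r.isolate_id, r.detail))
        elif r.section == "final":
            report.final.append(r.isolate_id)
        else:
            raise ValueError(f"{path}: unknown report section {r.section!r}")
    return report
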