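"""Schema-validated CSV readers/writers and run configuration.

All pipeline inputs are plain comma-separated tables with a one-line header.

Schema v1:

``peaks.csv``
    injection_id, run_order, role, compound, rt_min, area,
    delta_raw_permil, delta_sem_permil
``samples.csv``
    injection_id, strain, donor, sulfate_mM, bio_rep, water_delta_permil
``standards.csv``
    standard_name, compound, known_delta_permil, n_methyl_H_added
``od.csv``
    strain, donor, sulfate_mM, bio_rep, time_h, od600

Rows that fail to parse are collected into row-level error reports (with line
numbers) rather than aborting the whole file; a missing required column is a
schema error.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .types import (
    DeltaValue,
    Donor,
    DomainError,
    Injection,
    InjectionRole,
    PeakRecord,
    SampleCondition,
    Strain,
)

logger = logging.getLogger("lipid2h")


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


class SchemaError(ValueError):
    """The file header does not match the documented schema."""


@dataclass
class RowError:
    line: int
    message: str


@dataclass
class ParseReport:
    path: str
    n_rows: int = 0
    errors: list[RowError] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


PEAKS_COLUMNS = [
    "injection_id",
    "run_order",
    "role",
    "compound",
    "rt_min",
    "area",
    "delta_raw_permil",
    "delta_sem_permil",
]
SAMPLES_COLUMNS = [
    "injection_id",
    "strain",
    "donor",
    "sulfate_mM",
    "bio_rep",
    "water_delta_permil",
]
STANDARDS_COLUMNS = ["standard_name", "compound", "known_delta_permil", "n_methyl_H_added"]
OD_COLUMNS = ["strain", "donor", "sulfate_mM", "bio_rep", "time_h", "od600"]


def _check_header(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, required, str(path))
    return df


def _parse_float(text: str, what: str) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"non-numeric {what}: {text!r}") from None
    if not math.isfinite(value):
        raise ValueError(f"non-finite {what}: {text!r}")
    return value


def read_peak_table(path: str | Path) -> tuple[list[Injection], ParseReport]:
    """Read ``peaks.csv`` into run-ordered :class:`Injection` objects.

    Returns the injections plus a :class:`ParseReport`; malformed rows are
    reported with their 1-based line number (header = line 1) and skipped.
    """
    df = _read_csv(path, PEAKS_COLUMNS)
    report = ParseReport(path=str(path), n_rows=len(df))
    by_id: dict[str, Injection] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            run_order = int(row["run_order"])
            role = InjectionRole(row["role"])
            rt = _parse_float(row["rt_min"], "rt_min")
            area = _parse_float(row["area"], "area")
            raw = row["delta_raw_permil"].strip()
            delta = None
            if raw not in ("", "NA", "NaN", "nan"):
                sem_text = row["delta_sem_permil"].strip()
                sem = _parse_float(sem_text, "delta_sem_permil") if sem_text else 0.0
                delta = DeltaValue(
                    _parse_float(raw, "delta_raw_permil"),
                    reference="coinjected-ref",
                    sem=sem,
                )
            peak = PeakRecord(
                compound_label=row["compound"],
                retention_time=rt,
                area=area,
                raw_delta=delta,
            )
        except (ValueError, DomainError) as exc:
            report.errors.append(RowError(line=line, message=str(exc)))
            continue
        inj = by_id.get(row["injection_id"])
        if inj is None:
            inj = Injection(injection_id=row["injection_id"], run_order=run_order, role=role)
            by_id[inj.injection_id] = inj
        inj.peaks.append(peak)
    injections = sorted(by_id.values(), key=lambda i: i.run_order)
    orders = [i.run_order for i in injections]
    if len(set(orders)) != len(orders):
        raise SchemaError(f"{path}: run_order values are not unique per injection")
    if report.errors:
        for err in report.errors:
            logger.warning("%s line %d: %s", path, err.line, err.message)
    return injections, report


def write_peak_table(path: str | Path, injections: Iterable[Injection]) -> None:
    rows = []
    for inj in injections:
        for p in inj.peaks:
            rows.append(
                {
                    "injection_id": inj.injection_id,
                    "run_order": inj.run_order,
                    "role": inj.role.value,
                    "compound": p.compound_label,
                    "rt_min": repr(p.retention_time),
                    "area": repr(p.area),
                    "delta_raw_permil": "" if p.raw_delta is None else repr(p.raw_delta.value),
                    "delta_sem_permil": "" if p.raw_delta is None else repr(p.raw_delta.sem),
                }
            )
    pd.DataFrame(rows, columns=PEAKS_COLUMNS).to_csv(path, index=False)


def attach_samples(
    injections: list[Injection], samples_path: str | Path
) -> dict[str, float]:
    """Link sample injections to their conditions from ``samples.csv``.

    Returns a map injection_id → media-water δ²H (‰ vs V-SMOW).
    """
    df = _read_csv(samples_path, SAMPLES_COLUMNS)
    water: dict[str, float] = {}
    by_id = {inj.injection_id: inj for inj in injections}
    for _, row in df.iterrows():
        cond = SampleCondition(
            strain=Strain(row["strain"]),
            donor=Donor(row["donor"]),
            sulfate_mM=float(row["sulfate_mM"]),
            bio_replicate=int(row["bio_rep"]),
        )
        water[row["injection_id"]] = float(row["water_delta_permil"])
        inj = by_id.get(row["injection_id"])
        if inj is not None:
            inj.sample_link = cond
        else:
            logger.warning("samples.csv references unknown injection %s", row["injection_id"])
    return water


def read_standards(path: str | Path) -> pd.DataFrame:
    """Read ``standards.csv`` (known δ of standards, alkane ladder, FAME mix)."""
    df = _read_csv(path, STANDARDS_COLUMNS)
    out = df.copy()
    out["known_delta_permil"] = out["known_delta_permil"].map(
        lambda t: _parse_float(t, "known_delta_permil") if t.strip() else float("nan")
    )
    out["n_methyl_H_added"] = out["n_methyl_H_added"].map(
        lambda t: int(t) if t.strip() else 0
    )
    return out


def read_od_table(path: str | Path) -> pd.DataFrame:
    """Read ``od.csv`` growth curves as a typed DataFrame."""
    df = _read_csv(path, OD_COLUMNS)
    out = df.copy()
    for col in ("sulfate_mM", "time_h", "od600"):
        out[col] = out[col].map(lambda t, c=col: _parse_float(t, c))
    out["bio_rep"] = out["bio_rep"].map(int)
    return out


@dataclass
class RunConfig:
    """Run configuration (YAML on disk)."""

    seed: int = 0
    qc_threshold_permil: float = 7.0
    instrument_rms_permil: float = 5.5
    weighting: str = "hydrogen"  # or "abundance"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)
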