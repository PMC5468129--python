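"""Data model and CSV I/O for vial-structured life-history assays.

The experimental unit for time-to-event traits is a *vial*: a group of
flies inspected at irregular times, so each death (or eclosion) is known
only up to the inspection interval in which it was discovered, and flies
still alive (or uneclosed) at the final inspection are right-censored.
The on-disk format is a long CSV with one row per vial x interval; ragged
inspection schedules are therefore native.

Intervals are half-open ``(lo, hi]`` in hours from the trait-specific
clock start (start of starvation, end of cold shock, or egg-laying
midpoint), because an event is attributed to the inspection at which it
is discovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Closed label sets
# ---------------------------------------------------------------------------

#: Designated "not applicable" label for factors a trait does not use
#: (e.g. developmental time pools the sexes). Never silently dropped.
NOT_APPLICABLE = "NA"

REGIME_LEVELS = ("R", "U", "C")
SEX_LEVELS = ("F", "M")
CUE_LEVELS = ("none", "cold_shock")
STARV_LEVELS = ("none", "starved")
AGE_CLASS_LEVELS = ("early_4d", "early_7d", "midlife_14d")
TRAIT_LEVELS = (
    "feeding",
    "dry_weight",
    "wet_weight",
    "water_pct",
    "glycogen",
    "TAG",
    "body_glucose",
    "hemolymph_glucose",
    "trehalose",
)


class DataValidationError(ValueError):
    """Raised when a table or record violates the data model."""


def _check_level(value: str, levels: tuple[str, ...], name: str) -> str:
    if value not in levels and value != NOT_APPLICABLE:
        raise DataValidationError(
            f"{name}={value!r} not in {levels + (NOT_APPLICABLE,)}"
        )
    return value


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentCell:
    """One cell of the treatment design: selection regime x sex x cold-shock
    cue x starvation. Factors a trait does not use carry ``NOT_APPLICABLE``."""

    regime: str = NOT_APPLICABLE
    sex: str = NOT_APPLICABLE
    cue: str = NOT_APPLICABLE
    starv: str = NOT_APPLICABLE

    def __post_init__(self) -> None:
        _check_level(self.regime, REGIME_LEVELS, "regime")
        _check_level(self.sex, SEX_LEVELS, "sex")
        _check_level(self.cue, CUE_LEVELS, "cue")
        _check_level(self.starv, STARV_LEVELS, "starv")


@dataclass
class VialIntervalRecord:
    """One vial's interval-censored event counts.

    ``deaths[i]`` flies had their event in ``(boundaries[i-1], boundaries[i]]``
    (with an implicit lower edge at 0 for the first interval; latent times at
    or below the first boundary fall in the first interval) and ``n_censored``
    flies were still event-free at ``boundaries[-1]``.
    """

    vial_id: str
    line_id: int
    cell: TreatmentCell
    start_age_h: float
    n_start: int
    boundaries: tuple[float, ...]
    deaths: tuple[int, ...]
    n_censored: int

    def problems(self) -> list[str]:
        """All invariant violations for this record (empty list if valid)."""
        out: list[str] = []
        b = np.asarray(self.boundaries, dtype=float)
        d = np.asarray(self.deaths)
        if len(self.deaths) != len(self.boundaries):
            out.append(
                f"len(deaths)={len(self.deaths)} != len(boundaries)={len(self.boundaries)}"
            )
        if b.size and not np.all(b > 0):
            out.append("boundaries must be > 0")
        if b.size > 1 and not np.all(np.diff(b) > 0):
            out.append("boundaries not strictly increasing")
        if d.size and (np.any(d < 0) or np.any(d != np.round(d))):
            out.append("deaths must be non-negative integers")
        if self.n_censored < 0:
            out.append("n_censored must be >= 0")
        if self.n_start < 0:
            out.append("n_start must be >= 0")
        if int(np.sum(d)) + self.n_censored != self.n_start:
            out.append(
                f"counts do not sum to n_start "
                f"({int(np.sum(d))} + {self.n_censored} != {self.n_start})"
            )
        return out

    def validate(self) -> "VialIntervalRecord":
        probs = self.problems()
        if probs:
            raise DataValidationError(f"vial {self.vial_id}: " + "; ".join(probs))
        return self


@dataclass
class FecundityRecord:
    """One female's one-day (18 h) egg count with age class and treatment."""

    female_id: str
    line_id: int
    cell: TreatmentCell
    age_class: str
    eggs: int

    def problems(self) -> list[str]:
        out: list[str] = []
        if self.age_class not in AGE_CLASS_LEVELS:
            out.append(f"age_class={self.age_class!r} not in {AGE_CLASS_LEVELS}")
        if self.eggs < 0 or int(self.eggs) != self.eggs:
            out.append("eggs must be a non-negative integer")
        if self.cell.sex not in ("F", NOT_APPLICABLE):
            out.append("fecundity records are female-only")
        return out

    def validate(self) -> "FecundityRecord":
        probs = self.problems()
        if probs:
            raise DataValidationError(f"female {self.female_id}: " + "; ".join(probs))
        return self


@dataclass
class LineTraitRecord:
    """One physiology measurement: a single value per line x sex x trait."""

    line_id: int
    regime: str
    sex: str
    trait: str
    value: float

    def problems(self) -> list[str]:
        out: list[str] = []
        if self.regime not in REGIME_LEVELS:
            out.append(f"regime={self.regime!r} not in {REGIME_LEVELS}")
        if self.sex not in SEX_LEVELS:
            out.append(f"sex={self.sex!r} not in {SEX_LEVELS}")
        if self.trait not in TRAIT_LEVELS:
            out.append(f"trait={self.trait!r} not in {TRAIT_LEVELS}")
        if not np.isfinite(self.value):
            out.append("value must be finite")
        return out


@dataclass
class VialBinomialRecord:
    """Per-vial successes/trials, e.g. eclosed adults out of eggs laid."""

    vial_id: str
    line_id: int
    cell: TreatmentCell
    n_success: int
    n_total: int

    def problems(self) -> list[str]:
        out: list[str] = []
        if self.n_total < 0 or self.n_success < 0:
            out.append("counts must be >= 0")
        if self.n_success > self.n_total:
            out.append("n_success exceeds n_total")
        return out


# ---------------------------------------------------------------------------
# Column-mapping adapter (e.g. for externally deposited tables)
# ---------------------------------------------------------------------------


@dataclass
class ColumnMap:
    """Maps a foreign CSV schema onto the canonical one.

    ``columns`` maps canonical column names (see ``VIAL_COLUMNS``) to the
    source file's column names; ``levels`` optionally recodes factor values,
    e.g. ``{"cue": {"cs": "cold_shock"}}``. Intended for ingesting external
    deposits whose exact layout is configured by whoever holds the files.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    levels: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(columns=raw.get("columns", {}), levels=raw.get("levels", {}))

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.columns:
            rename = {src: canon for canon, src in self.columns.items()}
            df = df.rename(columns=rename)
        for col, mapping in self.levels.items():
            if col in df.columns:
                df[col] = df[col].map(lambda v: mapping.get(v, v))
        return df


# ---------------------------------------------------------------------------
# CSV I/O — vial interval tables
# ---------------------------------------------------------------------------

VIAL_COLUMNS = [
    "vial_id",
    "line_id",
    "regime",
    "sex",
    "cue",
    "starv",
    "start_age_h",
    "interval_lo_h",
    "interval_hi_h",
    "deaths",
    "n_censored",
]

FECUNDITY_COLUMNS = [
    "female_id",
    "line_id",
    "regime",
    "cue",
    "starv",
    "age_class",
    "eggs",
]

LINE_TRAIT_COLUMNS = ["line_id", "regime", "sex", "trait", "value"]

_READ_KW = dict(keep_default_na=False, na_values=[""], dtype=str)


def write_vial_table(records: Sequence[VialIntervalRecord], path: str | Path) -> Path:
    """Write vials to long-format CSV (one row per interval; ``n_censored``
    populated only on each vial's final row). Empty input yields a
    header-only file."""
    rows = []
    for r in records:
        lo = 0.0
        for i, hi in enumerate(r.boundaries):
            rows.append(
                {
                    "vial_id": r.vial_id,
                    "line_id": r.line_id,
                    "regime": r.cell.regime,
                    "sex": r.cell.sex,
                    "cue": r.cell.cue,
                    "starv": r.cell.starv,
                    "start_age_h": repr(float(r.start_age_h)),
                    "interval_lo_h": repr(float(lo)),
                    "interval_hi_h": repr(float(hi)),
                    "deaths": int(r.deaths[i]),
                    "n_censored": r.n_censored if i == len(r.boundaries) - 1 else "",
                }
            )
            lo = hi
    df = pd.DataFrame(rows, columns=VIAL_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_vial_table(
    path: str | Path, schema: ColumnMap | None = None
) -> list[VialIntervalRecord]:
    """Read a long-format vial CSV back into validated records.

    Raises :class:`DataValidationError` naming the offending vial on
    non-increasing boundaries or count mismatches.
    """
    df = pd.read_csv(path, **_READ_KW)
    if schema is not None:
        df = schema.apply(df)
    missing = [c for c in VIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing columns: {missing}")
    records: list[VialIntervalRecord] = []
    for vial_id, grp in df.groupby("vial_id", sort=False):
        lo = grp["interval_lo_h"].astype(float).to_numpy()
        hi = grp["interval_hi_h"].astype(float).to_numpy()
        if np.any(hi <= lo) or np.any(np.diff(hi) <= 0):
            raise DataValidationError(f"vial {vial_id}: boundaries not increasing")
        if not np.allclose(lo[1:], hi[:-1]):
            raise DataValidationError(f"vial {vial_id}: intervals do not chain")
        cens = grp["n_censored"].to_numpy()
        if pd.isna(cens[-1]):
            raise DataValidationError(f"vial {vial_id}: final row lacks n_censored")
        deaths = grp["deaths"].astype(int).tolist()
        first = grp.iloc[0]
        rec = VialIntervalRecord(
            vial_id=str(vial_id),
            line_id=int(first["line_id"]),
            cell=TreatmentCell(
                regime=first["regime"],
                sex=first["sex"],
                cue=first["cue"],
                starv=first["starv"],
            ),
            start_age_h=float(first["start_age_h"]),
            n_start=int(sum(deaths)) + int(float(cens[-1])),
            boundaries=tuple(float(x) for x in hi),
            deaths=tuple(deaths),
            n_censored=int(float(cens[-1])),
        )
        # n_start is reconstructed from counts, so re-check the sum against
        # an explicit column if the source provides one.
        rec.validate()
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# CSV I/O — fecundity and line-trait tables
# ---------------------------------------------------------------------------


def write_fecundity_table(
    records: Sequence[FecundityRecord], path: str | Path
) -> Path:
    rows = [
        {
            "female_id": r.female_id,
            "line_id": r.line_id,
            "regime": r.cell.regime,
            "cue": r.cell.cue,
            "starv": r.cell.starv,
            "age_class": r.age_class,
            "eggs": int(r.eggs),
        }
        for r in records
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=FECUNDITY_COLUMNS).to_csv(path, index=False)
    return path


def read_fecundity_table(
    path: str | Path, schema: ColumnMap | None = None
) -> list[FecundityRecord]:
    df = pd.read_csv(path, **_READ_KW)
    if schema is not None:
        df = schema.apply(df)
    missing = [c for c in FECUNDITY_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        rec = FecundityRecord(
            female_id=str(row["female_id"]),
            line_id=int(row["line_id"]),
            cell=TreatmentCell(
                regime=row["regime"], sex="F", cue=row["cue"], starv=row["starv"]
            ),
            age_class=row["age_class"],
            eggs=int(row["eggs"]),
        )
        rec.validate()
        out.append(rec)
    return out


def write_line_trait_table(
    records: Sequence[LineTraitRecord], path: str | Path
) -> Path:
    rows = [
        {
            "line_id": r.line_id,
            "regime": r.regime,
            "sex": r.sex,
            "trait": r.trait,
            "value": repr(float(r.value)),
        }
        for r in records
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=LINE_TRAIT_COLUMNS).to_csv(path, index=False)
    return path


def read_line_trait_table(
    path: str | Path, schema: ColumnMap | None = None
) -> list[LineTraitRecord]:
    df = pd.read_csv(path, **_READ_KW)
    if schema is not None:
        df = schema.apply(df)
    missing = [c for c in LINE_TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing columns: {missing}")
    return [
        LineTraitRecord(
            line_id=int(row["line_id"]),
            regime=row["regime"],
            sex=row["sex"],
            trait=row["trait"],
            value=float(row["value"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationIssue:
    record_id: str
    message: str


@dataclass
class ValidationReport:
    """Accumulated invariant violations; empty iff the dataset is valid."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def __str__(self) -> str:
        if self.ok:
            return "dataset valid"
        return "\n".join(f"{i.record_id}: {i.message}" for i in self.issues)


def validate_dataset(records: Iterable[VialIntervalRecord]) -> ValidationReport:
    """Collect every invariant violation (including duplicated vial ids)
    into a report; never raises."""
    report = ValidationReport()
    seen: set[str] = set()
    for r in records:
        if r.vial_id in seen:
            report.issues.append(ValidationIssue(r.vial_id, "duplicated vial_id"))
        seen.add(r.vial_id)
        for msg in r.problems():
            report.issues.append(ValidationIssue(r.vial_id, msg))
    return report


def validate_line_traits(records: Sequence[LineTraitRecord]) -> ValidationReport:
    """At most one record per (line, sex, trait); values finite."""
    report = ValidationReport()
    seen: set[tuple] = set()
    for r in records:
        key = (r.line_id, r.sex, r.trait)
        rid = f"line {r.line_id}/{r.sex}/{r.trait}"
        if key in seen:
            report.issues.append(ValidationIssue(rid, "duplicate measurement"))
        seen.add(key)
        for msg in r.problems():
            report.issues.append(ValidationIssue(rid, msg))
    return report
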