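"""Study-level data model, CSV I/O, packaged fixtures and subset selection.

Every analysis in this package starts from two-arm continuous summaries:
per arm a sample size, a mean and an SD.  Studies carry stratification
metadata (gestational timing, measurement level, confounder-exclusion flag)
used for subgroup and sensitivity analyses.
"""

from __future__ import annotations

import csv
import math
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path

from .exceptions import RowParseError, SchemaError, ValidationError

__all__ = [
    "ArmSummary",
    "StudyRecord",
    "StudyCollection",
    "Timing",
    "Level",
    "ExcludesConfounders",
    "read_study_table",
    "write_study_table",
    "load_gdf15_fixture",
    "load_gdf15_table",
    "filter_studies",
    "REQUIRED_COLUMNS",
]


class Timing(str, Enum):
    """Gestational timing stratum; samples taken at delivery count as late."""

    MIDDLE = "middle"
    LATE = "late"


class Level(str, Enum):
    """Measurement level of the marker."""

    MRNA = "mRNA"
    PROTEIN = "protein"


class ExcludesConfounders(str, Enum):
    """Whether the study excluded confounding conditions at sample selection."""

    YES = "yes"
    NO = "no"
    NOT_AVAILABLE = "not_available"


@dataclass(frozen=True)
class ArmSummary:
    """Summary statistics for one study arm.

    Parameters
    ----------
    n : int
        Number of subjects, at least 1.
    mean : float
        Arm mean in the study's measurement units.
    sd : float
        Arm standard deviation, non-negative.
    """

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, int) and self.n >= 1):
            raise ValidationError(f"arm n must be a positive integer, got {self.n!r}")
        if not math.isfinite(self.mean):
            raise ValidationError(f"arm mean must be finite, got {self.mean!r}")
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise ValidationError(f"arm sd must be finite and >= 0, got {self.sd!r}")


@dataclass(frozen=True)
class StudyRecord:
    """One two-arm study (or one timing stratum of a multi-stratum study)."""

    study_id: str
    timing: Timing
    level: Level
    case: ArmSummary
    control: ArmSummary
    sample_type: str = ""
    country_year: str = ""
    diagnostic_criteria: str = ""
    excludes_confounders: ExcludesConfounders = ExcludesConfounders.NOT_AVAILABLE

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")

    @property
    def key(self) -> tuple[str, Timing]:
        return (self.study_id, self.timing)


@dataclass
class StudyCollection:
    """An ordered collection of studies; order defines forest-table order."""

    records: list[StudyRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (study_id, timing) keys: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> StudyRecord:
        return self.records[i]

    @property
    def total_case_n(self) -> int:
        return sum(r.case.n for r in self.records)

    @property
    def total_control_n(self) -> int:
        return sum(r.control.n for r in self.records)


REQUIRED_COLUMNS = (
    "study_id",
    "timing",
    "level",
    "n_case",
    "mean_case",
    "sd_case",
    "n_control",
    "mean_control",
    "sd_control",
)

_OPTIONAL_COLUMNS = (
    "sample_type",
    "country_year",
    "diagnostic_criteria",
    "excludes_confounders",
)


def _parse_int(value: str, column: str, row: int) -> int:
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise RowParseError(row, f"column {column!r}: {value!r} is not an integer") from None
    if out <= 0:
        raise RowParseError(row, f"column {column!r}: sample size must be positive, got {out}")
    return out


def _parse_float(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowParseError(row, f"column {column!r}: {value!r} is not numeric") from None


def _parse_enum(enum_cls, value: str, column: str, row: int):
    try:
        return enum_cls(value)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise RowParseError(row, f"column {column!r}: {value!r} not one of {{{valid}}}") from None


def read_study_table(path: str | Path) -> StudyCollection:
    """Read a study table from a headered CSV file.

    Required columns: study_id, timing, level, n_case, mean_case, sd_case,
    n_control, mean_control, sd_control.  Optional metadata columns
    (sample_type, country_year, diagnostic_criteria, excludes_confounders)
    default to empty / not-available when absent or blank.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    RowParseError
        If a data row contains a non-numeric or non-positive count; the
        error names the offending 1-based data-row number.
    ValidationError
        If a parsed value violates a domain invariant (e.g. sd < 0).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        return _read_study_rows(csv.DictReader(fh), provenance=str(path))


def _read_study_rows(reader: csv.DictReader, provenance: str) -> StudyCollection:
    header = reader.fieldnames or []
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    for i, row in enumerate(reader, start=1):
        study_id = (row.get("study_id") or "").strip()
        if not study_id:
            raise RowParseError(i, "study_id is empty")
        timing = _parse_enum(Timing, (row.get("timing") or "").strip(), "timing", i)
        level = _parse_enum(Level, (row.get("level") or "").strip(), "level", i)
        case = ArmSummary(
            n=_parse_int(row["n_case"], "n_case", i),
            mean=_parse_float(row["mean_case"], "mean_case", i),
            sd=_parse_float(row["sd_case"], "sd_case", i),
        )
        control = ArmSummary(
            n=_parse_int(row["n_control"], "n_control", i),
            mean=_parse_float(row["mean_control"], "mean_control", i),
            sd=_parse_float(row["sd_control"], "sd_control", i),
        )
        excl_raw = (row.get("excludes_confounders") or "").strip()
        excl = (
            _parse_enum(ExcludesConfounders, excl_raw, "excludes_confounders", i)
            if excl_raw
            else ExcludesConfounders.NOT_AVAILABLE
        )
        records.append(
            StudyRecord(
                study_id=study_id,
                timing=timing,
                level=level,
                case=case,
                control=control,
                sample_type=(row.get("sample_type") or "").strip(),
                country_year=(row.get("country_year") or "").strip(),
                diagnostic_criteria=(row.get("diagnostic_criteria") or "").strip(),
                excludes_confounders=excl,
            )
        )
    return StudyCollection(records=records, provenance=provenance)


def write_study_table(collection: StudyCollection, path: str | Path) -> None:
    """Write a StudyCollection to CSV, round-trippable via read_study_table."""
    path = Path(path)
    columns = list(REQUIRED_COLUMNS[:3]) + list(_OPTIONAL_COLUMNS) + list(REQUIRED_COLUMNS[3:])
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for r in collection:
            writer.writerow(
                {
                    "study_id": r.study_id,
                    "timing": r.timing.value,
                    "level": r.level.value,
                    "sample_type": r.sample_type,
                    "country_year": r.country_year,
                    "diagnostic_criteria": r.diagnostic_criteria,
                    "excludes_confounders": r.excludes_confounders.value,
                    "n_case": r.case.n,
                    "mean_case": repr(r.case.mean),
                    "sd_case": repr(r.case.sd),
                    "n_control": r.control.n,
                    "mean_control": repr(r.control.mean),
                    "sd_control": repr(r.control.sd),
                }
            )


_FIXTURE_FILES = {Level.MRNA: "mrna_studies.csv", Level.PROTEIN: "protein_studies.csv"}


def load_gdf15_table(level: Level | str) -> StudyCollection:
    """Load the full packaged GDF-15 study table for one measurement level."""
    level = Level(level)
    name = _FIXTURE_FILES[level]
    source = resources.files("metasmd.data").joinpath(name)
    with source.open(newline="", encoding="utf-8") as fh:
        return _read_study_rows(csv.DictReader(fh), provenance=f"packaged:{name}")


def load_gdf15_fixture(level: Level | str, timing: Timing | str) -> StudyCollection:
    """Load one (level, timing) stratum of the packaged GDF-15 study data.

    Strata sizes: (mRNA, late) has 12 records, (mRNA, middle) 1,
    (protein, late) 4, (protein, middle) 3.
    """
    level = Level(level)
    timing = Timing(timing)
    table = load_gdf15_table(level)
    return filter_studies(table, timing=timing)


def filter_studies(
    collection: StudyCollection,
    *,
    timing: Timing | str | None = None,
    level: Level | str | None = None,
    excludes_confounders: ExcludesConfounders | str | None = None,
    study_ids: Iterable[str] | Sequence[str] | None = None,
) -> StudyCollection:
    """Select a subset of studies by metadata, preserving input order.

    All given criteria must hold (conjunction); an empty result is valid.
    """
    timing = Timing(timing) if timing is not None else None
    level = Level(level) if level is not None else None
    excl = (
        ExcludesConfounders(excludes_confounders)
        if excludes_confounders is not None
        else None
    )
    ids = set(study_ids) if study_ids is not None else None

    def keep(r: StudyRecord) -> bool:
        if timing is not None and r.timing is not timing:
            return False
        if level is not None and r.level is not level:
            return False
        if excl is not None and r.excludes_confounders is not excl:
            return False
        if ids is not None and r.study_id not in ids:
            return False
        return True

    return StudyCollection(
        records=[r for r in collection if keep(r)],
        provenance=collection.provenance,
    )
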