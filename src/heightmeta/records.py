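"""Study-level data model: one row per published within-pair height correlation.

A study record carries the observed Pearson correlation between spouses'
heights, the number of couples it was computed on, how that number was
obtained (directly reported, recovered from a standard error or a
p-value category, imputed, ...), and the grouping fields the multilevel
model needs: the author group (publications from the same team share a
level) and the country, with its UN M49 code from which the binary
western moderator is derived.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import m49

CSV_COLUMNS = [
    "record_id",
    "source_label",
    "author_group_id",
    "country_name",
    "un_region_code",
    "year_published",
    "r_observed",
    "n_couples",
    "n_provenance",
    "p_category",
    "se_reported",
]


class NProvenance(str, enum.Enum):
    """How the couples count N was obtained for a record."""

    REPORTED = "reported"
    RANGE_MIDPOINT = "range_midpoint"
    CHILDREN_COUNT = "children_count"
    MINIMUM_REPORTED = "minimum_reported"
    FROM_SE = "from_se"
    FROM_P_CATEGORY = "from_p_category"
    MEDIAN_IMPUTED = "median_imputed"


class PCategory(str, enum.Enum):
    """Significance category reported in lieu of N or SE."""

    P_LT_05 = "p_lt_05"
    P_LT_01 = "p_lt_01"
    P_LT_001 = "p_lt_001"


class ValidationError(ValueError):
    """Raised when an input table violates the record invariants.

    ``errors`` holds one row-indexed message per violation.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def classify_western(un_region_code: int, country_override: bool | None = None) -> bool:
    """Geographic western/non-western coding from an M49 code.

    True iff the code resolves to Europe (150), Northern America (021)
    or Australia and New Zealand (053).  Japan (392) is non-western by
    the explicit convention this scheme follows, which the packaged
    table already encodes (Japan sits under Asia).  ``country_override``
    short-circuits the lookup for ad-hoc corrections.
    """
    if country_override is not None:
        return bool(country_override)
    bucket = m49.resolve_bucket(un_region_code)
    return bucket in m49.WESTERN_REGIONS


@dataclass
class StudyRecord:
    record_id: str
    source_label: str
    author_group_id: str
    country_name: str
    un_region_code: int
    year_published: int
    r_observed: float
    n_couples: int
    n_provenance: NProvenance = NProvenance.REPORTED
    p_category: PCategory | None = None
    se_reported: float | None = None
    western: bool = field(default=False)

    def __post_init__(self) -> None:
        self.n_provenance = NProvenance(self.n_provenance)
        if self.p_category is not None:
            self.p_category = PCategory(self.p_category)

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        if not (-1.0 < self.r_observed < 1.0):
            errs.append(f"r_observed={self.r_observed} outside (-1, 1)")
        if self.n_couples < 4:
            errs.append(
                f"n_couples={self.n_couples} < 4 (sampling variance 1/(N-3) undefined)"
            )
        has_p = self.p_category is not None
        if has_p != (self.n_provenance is NProvenance.FROM_P_CATEGORY):
            errs.append("p_category present iff n_provenance == from_p_category")
        has_se = self.se_reported is not None
        if has_se != (self.n_provenance is NProvenance.FROM_SE):
            errs.append("se_reported present iff n_provenance == from_se")
        if has_se and self.se_reported <= 0:
            errs.append(f"se_reported={self.se_reported} must be positive")
        try:
            m49.resolve_bucket(self.un_region_code)
        except KeyError as exc:
            errs.append(str(exc))
        return errs


@dataclass
class Dataset:
    """Ordered, validated collection of study records."""

    records: list[StudyRecord]

    @property
    def mean_year(self) -> float:
        if not self.records:
            raise ValueError("empty dataset has no mean year")
        return float(np.mean([rec.year_published for rec in self.records]))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "record_id": rec.record_id,
                    "source_label": rec.source_label,
                    "author_group_id": rec.author_group_id,
                    "country_name": rec.country_name,
                    "un_region_code": rec.un_region_code,
                    "year_published": rec.year_published,
                    "r_observed": rec.r_observed,
                    "n_couples": rec.n_couples,
                    "n_provenance": rec.n_provenance.value,
                    "p_category": rec.p_category.value if rec.p_category else "",
                    "se_reported": "" if rec.se_reported is None else rec.se_reported,
                    "western": rec.western,
                }
            )
        return pd.DataFrame(rows)


def _parse_row(idx, row) -> StudyRecord:
    def opt(key):
        val = row.get(key)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            return None
        return val

    se = opt("se_reported")
    return StudyRecord(
        record_id=str(row["record_id"]),
        source_label=str(row["source_label"]),
        author_group_id=str(row["author_group_id"]),
        country_name=str(row["country_name"]),
        un_region_code=int(row["un_region_code"]),
        year_published=int(row["year_published"]),
        r_observed=float(row["r_observed"]),
        n_couples=int(row["n_couples"]),
        n_provenance=NProvenance(str(row["n_provenance"])),
        p_category=PCategory(str(opt("p_category"))) if opt("p_category") else None,
        se_reported=float(se) if se is not None else None,
    )


def build_dataset(records: Iterable[StudyRecord]) -> Dataset:
    """Validate records, populate ``western``, and assemble a Dataset."""
    errors: list[str] = []
    out: list[StudyRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(records):
        errs = [f"row {i} ({rec.record_id}): {e}" for e in rec.validation_errors()]
        if rec.record_id in seen:
            errs.append(f"row {i}: duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
        if errs:
            errors.extend(errs)
            continue
        out.append(replace(rec, western=classify_western(rec.un_region_code)))
    if errors:
        raise ValidationError(errors)
    if not out:
        raise ValidationError(["dataset contains no records"])
    return Dataset(out)


def read_studies(path: str | Path) -> Dataset:
    """Read and validate the canonical study CSV.

    UTF-8, comma separated, dot decimals, header required.  Rows that
    violate any invariant are collected and reported together in a
    :class:`ValidationError` with row-indexed messages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"record_id": str, "author_group_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c not in ("p_category", "se_reported")]
    if missing:
        raise ValidationError([f"missing required column(s): {', '.join(missing)}"])
    for optional in ("p_category", "se_reported"):
        if optional not in df.columns:
            df[optional] = ""
    records: list[StudyRecord] = []
    parse_errors: list[str] = []
    for i, row in df.iterrows():
        try:
            records.append(_parse_row(i, row))
        except (ValueError, KeyError, TypeError) as exc:
            parse_errors.append(f"row {i}: unparseable ({exc})")
    if parse_errors:
        raise ValidationError(parse_errors)
    return build_dataset(records)


def write_studies(ds: Dataset, path: str | Path) -> None:
    """Write the canonical CSV (round-trips through :func:`read_studies`)."""
    df = ds.to_frame().drop(columns=["western"])
    df.to_csv(path, index=False)


def validation_report(ds: Dataset) -> dict:
    """JSON-serialisable summary of a validated dataset."""
    westerns = [rec for rec in ds if rec.western]
    return {
        "n_records": len(ds),
        "n_author_groups": len({rec.author_group_id for rec in ds}),
        "n_countries": len({rec.country_name for rec in ds}),
        "n_western_countries": len({rec.country_name for rec in westerns}),
        "n_western_records": len(westerns),
        "mean_year": ds.mean_year,
        "year_range": [
            min(rec.year_published for rec in ds),
            max(rec.year_published for rec in ds),
        ],
        "n_range": [min(rec.n_couples for rec in ds), max(rec.n_couples for rec in ds)],
    }


def write_validation_report(ds: Dataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(validation_report(ds), indent=2, sort_keys=True))


def center_year(ds: Dataset) -> np.ndarray:
    """Mean-centered publication-year moderator, in dataset order.

    Centered at the analyzed dataset's own mean year; the mean used is
    recorded in fit metadata downstream.  Values sum to zero.
    """
    if not ds.records:
        raise ValueError("cannot center years of an empty dataset")
    years = np.array([rec.year_published for rec in ds], dtype=float)
    return years - years.mean()
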