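"""Cohort data model for a colorectal-cancer (CRC) case series.

One :class:`PatientRecord` per incident CRC case, with the derivation rules
used throughout the package:

* TNM stage collapses to two categories: I/II -> ``early``, III/IV -> ``late``.
* Tumour side is derived from lesion locations relative to the splenic
  flexure: a case is ``right``-sided if *any* lesion lies proximal to the
  flexure (synchronous rule), otherwise ``left``.
* Blood-count history in a look-back window before the presentation period
  classifies a case as ``done_normal`` / ``done_low`` / ``not_done`` against
  an anaemia threshold (default 110 g/l; a value exactly at the threshold
  counts as normal).

Cohorts round-trip losslessly through a plain CSV schema, and an exclusion
filter removes flagged records (incomplete, metachronous duplicates, other
neoplasms, non-incident cases, incidental/follow-up diagnoses) while
tallying counts per category.
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

SEXES = ("M", "F")
PATHWAYS = ("IDA", "BCSP", "SYMPTOMATIC")
TNM_STAGES = ("I", "II", "III", "IV")
LOCATION_TOKENS = ("PROX", "DIST")
EXCLUSION_CATEGORIES = (
    "incomplete",
    "metachronous_duplicate",
    "other_neoplasm",
    "non_incident",
    "incidental_or_followup",
)
BLOOD_COUNT_CLASSES = ("done_normal", "done_low", "not_done")

#: Default anaemia threshold for a prior blood count, g/l.
DEFAULT_HB_THRESHOLD = 110.0
#: Default comparison window for prior blood counts, months before the
#: presentation period.
DEFAULT_WINDOW_MONTHS = 24
#: Length of the presentation period (months immediately before diagnosis)
#: excluded from the look-back; timing offsets are stored relative to the
#: start of this period, so it enters only as documentation of the origin.
PRESENTATION_PERIOD_MONTHS = 3

CSV_COLUMNS = (
    "id",
    "age",
    "sex",
    "hb_g_l",
    "pathway",
    "tnm_stage",
    "locations",
    "prior_bc_months",
    "prior_bc_hb_g_l",
    "exclusion",
)


class CohortError(ValueError):
    """Base class for cohort data errors."""


class SchemaError(CohortError):
    """The CSV header does not match the cohort schema."""


class ParseError(CohortError):
    """A cell failed to parse; the message names the row and column."""


def derive_stage_category(tnm_stage: str) -> str:
    """Collapse a TNM stage to ``early`` (I, II) or ``late`` (III, IV)."""
    if tnm_stage in ("I", "II"):
        return "early"
    if tnm_stage in ("III", "IV"):
        return "late"
    raise CohortError(f"invalid TNM stage {tnm_stage!r}; expected one of {TNM_STAGES}")


def derive_side(tumour_locations: Sequence[str]) -> str:
    """Derive tumour side from lesion locations.

    ``right`` if any lesion is proximal to the splenic flexure (``PROX``),
    otherwise ``left``; synchronous lesions therefore inherit the most
    proximal side.
    """
    if not tumour_locations:
        raise CohortError("tumour_locations must be non-empty to derive side")
    for loc in tumour_locations:
        if loc not in LOCATION_TOKENS:
            raise CohortError(f"invalid location token {loc!r}; expected PROX or DIST")
    return "right" if "PROX" in tumour_locations else "left"


@dataclass(frozen=True)
class PriorBloodCount:
    """Last blood count in the look-back window before the presentation period.

    ``months_before_presentation`` counts back from the start of the
    3-month presentation period (0 = at its start), not from diagnosis.
    """

    months_before_presentation: float
    hb_g_l: float

    def __post_init__(self) -> None:
        if self.months_before_presentation < 0:
            raise CohortError(
                "prior blood count months offset must be non-negative, got "
                f"{self.months_before_presentation}"
            )
        if not self.hb_g_l > 0:
            raise CohortError(f"prior blood count Hb must be positive, got {self.hb_g_l}")


@dataclass(frozen=True)
class PatientRecord:
    """One incident CRC case."""

    id: str
    age: float
    sex: str
    hb_g_l: float
    pathway: str
    tnm_stage: str
    tumour_locations: tuple[str, ...]
    prior_blood_count: Optional[PriorBloodCount] = None
    exclusion: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise CohortError(f"record {self.id}: age must be positive, got {self.age}")
        if not self.hb_g_l > 0:
            raise CohortError(f"record {self.id}: Hb must be positive, got {self.hb_g_l}")
        if self.sex not in SEXES:
            raise CohortError(f"record {self.id}: invalid sex {self.sex!r}")
        if self.pathway not in PATHWAYS:
            raise CohortError(f"record {self.id}: invalid pathway {self.pathway!r}")
        if self.tnm_stage not in TNM_STAGES:
            raise CohortError(f"record {self.id}: invalid TNM stage {self.tnm_stage!r}")
        if self.exclusion is not None and self.exclusion not in EXCLUSION_CATEGORIES:
            raise CohortError(
                f"record {self.id}: invalid exclusion category {self.exclusion!r}"
            )
        # Included records must carry at least one lesion location; flagged
        # (excluded) records may be incomplete.
        if self.exclusion is None and not self.tumour_locations:
            raise CohortError(f"record {self.id}: tumour_locations must be non-empty")
        for loc in self.tumour_locations:
            if loc not in LOCATION_TOKENS:
                raise CohortError(f"record {self.id}: invalid location token {loc!r}")

    @property
    def stage_category(self) -> str:
        return derive_stage_category(self.tnm_stage)

    @property
    def side(self) -> str:
        return derive_side(self.tumour_locations)


def classify_blood_count_history(
    record: PatientRecord,
    window_months: float = DEFAULT_WINDOW_MONTHS,
    hb_threshold: float = DEFAULT_HB_THRESHOLD,
) -> str:
    """Classify a case by the outcome of its last prior blood count.

    ``not_done`` if there is no prior count or it falls outside the window;
    ``done_low`` if the count is within the window with Hb strictly below
    the threshold; ``done_normal`` otherwise (Hb at or above the threshold).
    """
    if not window_months > 0:
        raise CohortError(f"window_months must be positive, got {window_months}")
    if not hb_threshold > 0:
        raise CohortError(f"hb_threshold must be positive, got {hb_threshold}")
    pbc = record.prior_blood_count
    if pbc is None or pbc.months_before_presentation > window_months:
        return "not_done"
    return "done_low" if pbc.hb_g_l < hb_threshold else "done_normal"


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of patient records with unique ids."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise CohortError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "Cohort":
        return Cohort(tuple(r for r in self.records if predicate(r)), self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with derived fields populated for included records."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "age": r.age,
                    "sex": r.sex,
                    "hb_g_l": r.hb_g_l,
                    "pathway": r.pathway,
                    "tnm_stage": r.tnm_stage,
                    "stage_category": r.stage_category,
                    "side": r.side if r.tumour_locations else None,
                    "prior_bc_months": (
                        r.prior_blood_count.months_before_presentation
                        if r.prior_blood_count
                        else math.nan
                    ),
                    "prior_bc_hb_g_l": (
                        r.prior_blood_count.hb_g_l if r.prior_blood_count else math.nan
                    ),
                    "exclusion": r.exclusion,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExclusionReport:
    """Tally of records removed by the exclusion filter, by category."""

    counts: dict[str, int]
    n_input: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + sum(self.counts.values()):
            raise CohortError("exclusion report counts do not sum to n_input")

    def to_json(self) -> str:
        payload = {c: self.counts.get(c, 0) for c in EXCLUSION_CATEGORIES}
        payload["n_input"] = self.n_input
        payload["n_retained"] = self.n_retained
        return json.dumps(payload, indent=2)


def apply_exclusions(raw: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Remove flagged records, preserving order, and tally each category."""
    counts = {c: 0 for c in EXCLUSION_CATEGORIES}
    kept = []
    for r in raw.records:
        if r.exclusion is None:
            kept.append(r)
        else:
            counts[r.exclusion] += 1
    report = ExclusionReport(counts=counts, n_input=len(raw), n_retained=len(kept))
    return Cohort(tuple(kept), raw.provenance), report


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    # repr of a Python float is shortest-exact, so read_cohort(write_cohort)
    # is bit-identical.
    return repr(float(x))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the package CSV schema (UTF-8, '.' decimal)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in cohort.records:
            pbc = r.prior_blood_count
            writer.writerow(
                [
                    r.id,
                    _fmt_float(r.age),
                    r.sex,
                    _fmt_float(r.hb_g_l),
                    r.pathway,
                    r.tnm_stage,
                    ";".join(r.tumour_locations),
                    _fmt_float(pbc.months_before_presentation) if pbc else "",
                    _fmt_float(pbc.hb_g_l) if pbc else "",
                    r.exclusion or "",
                ]
            )


def _parse_float(cell: str, row: int, col: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"row {row}: cannot parse column {col!r} value {cell!r}") from None


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV, validating the schema and every cell.

    Raises :class:`SchemaError` naming any missing or unexpected column, and
    :class:`ParseError` naming the row and column of any bad cell.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        missing = [c for c in CSV_COLUMNS if c not in header]
        extra = [c for c in header if c not in CSV_COLUMNS]
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing column(s) {missing}")
            if extra:
                parts.append(f"unexpected column(s) {extra}")
            raise SchemaError(f"{path}: " + "; ".join(parts))
        idx = {c: header.index(c) for c in CSV_COLUMNS}
        records = []
        for i, cells in enumerate(reader, start=1):
            if len(cells) != len(header):
                raise ParseError(f"row {i}: expected {len(header)} cells, got {len(cells)}")
            get = lambda c: cells[idx[c]]  # noqa: E731
            months_cell = get("prior_bc_months").strip()
            hb_cell = get("prior_bc_hb_g_l").strip()
            if bool(months_cell) != bool(hb_cell):
                raise ParseError(
                    f"row {i}: prior_bc_months and prior_bc_hb_g_l must both be "
                    "present or both empty"
                )
            pbc = None
            if months_cell:
                pbc = PriorBloodCount(
                    _parse_float(months_cell, i, "prior_bc_months"),
                    _parse_float(hb_cell, i, "prior_bc_hb_g_l"),
                )
            loc_cell = get("locations").strip()
            locations = tuple(t for t in loc_cell.split(";") if t) if loc_cell else ()
            excl = get("exclusion").strip() or None
            try:
                rec = PatientRecord(
                    id=get("id"),
                    age=_parse_float(get("age"), i, "age"),
                    sex=get("sex"),
                    hb_g_l=_parse_float(get("hb_g_l"), i, "hb_g_l"),
                    pathway=get("pathway"),
                    tnm_stage=get("tnm_stage"),
                    tumour_locations=locations,
                    prior_blood_count=pbc,
                    exclusion=excl,
                )
            except CohortError as err:
                raise ParseError(f"row {i}: {err}") from None
            records.append(rec)
    return Cohort(tuple(records), provenance=f"read from {path}")
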