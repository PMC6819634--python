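"""Six-wave cohort data model, CSV ingest/egest and eligibility filtering.

The cohort holds one record per woman with her answers to the lifetime
intimate-partner-violence (IPV) item at each of six survey waves
(1996, 2004, 2007, 2010, 2013, 2016), per-wave relationship-status and
stress items, and two baseline covariates (area of residence, highest
qualification).  Waves are indexed 1..6 internally; the source study
numbers the same occasions 1, 4, 5, 6, 7, 8, and both labellings are
exposed for provenance.

Eligibility for the consistency analysis requires an answer to the IPV
item at wave 1 and at least two of waves 2..6 (hence at least three
answers overall).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "N_WAVES",
    "WAVE_LABELS",
    "SOURCE_SURVEY_NUMBERS",
    "Response",
    "AREA_LEVELS",
    "QUAL_LEVELS",
    "REL_LEVELS",
    "SEP_DIV",
    "WomanRecord",
    "Cohort",
    "ExclusionSummary",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "is_eligible",
    "filter_eligible",
    "parse_pattern",
    "pattern_string",
]

N_WAVES = 6

#: internal wave index -> calendar year of the survey
WAVE_LABELS = {1: "1996", 2: "2004", 3: "2007", 4: "2010", 5: "2013", 6: "2016"}

#: internal wave index -> survey number used by the source cohort study
SOURCE_SURVEY_NUMBERS = {1: 1, 2: 4, 3: 5, 4: 6, 5: 7, 6: 8}


class Response(Enum):
    """One answer to the lifetime IPV item at one wave."""

    YES = "Y"
    NO = "N"
    MISSING = ""

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("Response has no truth value; compare explicitly")


AREA_LEVELS = ["major_city", "inner_regional", "outer_regional", "remote_very_remote"]
QUAL_LEVELS = ["lt_year12", "year12", "trade_cert_diploma", "university"]
REL_LEVELS = ["married", "defacto", "separated", "divorced", "widowed", "single"]
SEP_DIV = frozenset({"separated", "divorced"})

_IPV_CODES = {"Y": Response.YES, "N": Response.NO, "": Response.MISSING}
_BOOL_CODES = {"Y": True, "N": False, "": None}


class SchemaError(ValueError):
    """The CSV header does not match the documented wide schema."""


class ValidationError(ValueError):
    """A cell holds an unknown code, or ids are duplicated."""


@dataclass(frozen=True)
class WomanRecord:
    """One participant: id, six-wave IPV answers, covariate items."""

    id: str
    ipv: tuple[Response, ...]
    area: Optional[str] = None
    qualification: Optional[str] = None
    relationship_status: tuple[Optional[str], ...] = (None,) * N_WAVES
    partner_stress_high: tuple[Optional[bool], ...] = (None,) * N_WAVES
    income_stress_high: tuple[Optional[bool], ...] = (None,) * N_WAVES

    def __post_init__(self) -> None:
        for name in ("ipv", "relationship_status", "partner_stress_high", "income_stress_high"):
            if len(getattr(self, name)) != N_WAVES:
                raise ValidationError(f"{name} must have length {N_WAVES} (id={self.id!r})")
        if self.area is not None and self.area not in AREA_LEVELS:
            raise ValidationError(f"unknown area code {self.area!r} (id={self.id!r})")
        if self.qualification is not None and self.qualification not in QUAL_LEVELS:
            raise ValidationError(f"unknown qualification code {self.qualification!r} (id={self.id!r})")
        for s in self.relationship_status:
            if s is not None and s not in REL_LEVELS:
                raise ValidationError(f"unknown relationship code {s!r} (id={self.id!r})")

    @property
    def answered_count(self) -> int:
        return sum(1 for r in self.ipv if r is not Response.MISSING)


class Cohort:
    """Ordered collection of :class:`WomanRecord` with unique ids."""

    def __init__(self, records: Iterable[WomanRecord], provenance: str = "") -> None:
        self.records: list[WomanRecord] = list(records)
        self.provenance = provenance
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValidationError(f"duplicate id {r.id!r}")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[WomanRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> WomanRecord:
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row-per-woman DataFrame in the on-disk column layout."""
        rows = []
        for r in self.records:
            row: dict[str, str] = {"id": r.id}
            for w in range(N_WAVES):
                row[f"ipv_w{w + 1}"] = r.ipv[w].value
                row[f"rel_w{w + 1}"] = r.relationship_status[w] or ""
                row[f"pstress_w{w + 1}"] = _bool_code(r.partner_stress_high[w])
                row[f"istress_w{w + 1}"] = _bool_code(r.income_stress_high[w])
            row["area"] = r.area or ""
            row["qual"] = r.qualification or ""
            rows.append(row)
        return pd.DataFrame(rows, columns=_COLUMNS, dtype=str)


def _bool_code(v: Optional[bool]) -> str:
    return "" if v is None else ("Y" if v else "N")


_COLUMNS = (
    ["id"]
    + [f"ipv_w{w}" for w in range(1, N_WAVES + 1)]
    + [f"rel_w{w}" for w in range(1, N_WAVES + 1)]
    + [f"pstress_w{w}" for w in range(1, N_WAVES + 1)]
    + [f"istress_w{w}" for w in range(1, N_WAVES + 1)]
    + ["area", "qual"]
)


def _decode(cell: str, codes: dict, column: str, row_id: str):
    try:
        return codes[cell]
    except KeyError:
        raise ValidationError(f"unknown code {cell!r} in column {column} (id={row_id!r})") from None


def read_cohort(path: str | Path, dialect: Optional[dict] = None) -> Cohort:
    """Read a wide cohort CSV (one row per woman; empty cell = missing).

    ``dialect`` may override categorical code maps, e.g.
    ``{"area_codes": {"MC": "major_city", ...}}``; by default cells hold the
    level names themselves (see ``docs/data_dictionary.md``).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {', '.join(missing_cols)}")

    dialect = dialect or {}
    area_codes = {**{a: a for a in AREA_LEVELS}, "": None, **dialect.get("area_codes", {})}
    qual_codes = {**{q: q for q in QUAL_LEVELS}, "": None, **dialect.get("qual_codes", {})}
    rel_codes = {**{s: s for s in REL_LEVELS}, "": None, **dialect.get("rel_codes", {})}

    records = []
    for _, row in df.iterrows():
        rid = row["id"]
        records.append(
            WomanRecord(
                id=rid,
                ipv=tuple(_decode(row[f"ipv_w{w}"], _IPV_CODES, f"ipv_w{w}", rid) for w in range(1, 7)),
                area=_decode(row["area"], area_codes, "area", rid),
                qualification=_decode(row["qual"], qual_codes, "qual", rid),
                relationship_status=tuple(
                    _decode(row[f"rel_w{w}"], rel_codes, f"rel_w{w}", rid) for w in range(1, 7)
                ),
                partner_stress_high=tuple(
                    _decode(row[f"pstress_w{w}"], _BOOL_CODES, f"pstress_w{w}", rid) for w in range(1, 7)
                ),
                income_stress_high=tuple(
                    _decode(row[f"istress_w{w}"], _BOOL_CODES, f"istress_w{w}", rid) for w in range(1, 7)
                ),
            )
        )
    return Cohort(records, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort back to the same wide CSV dialect (lossless)."""
    cohort.to_frame().to_csv(path, index=False)


def is_eligible(record: WomanRecord) -> bool:
    """Wave-1 IPV answered and at least two of waves 2..6 answered."""
    if record.ipv[0] is Response.MISSING:
        return False
    later = sum(1 for r in record.ipv[1:] if r is not Response.MISSING)
    return later >= 2


@dataclass
class ExclusionSummary:
    """Bookkeeping for the eligibility filter.

    Wave-1 prevalences are percentages of YES among women who answered the
    IPV item at wave 1, reported separately for the included and excluded
    groups (``None`` when no such women exist).
    """

    n_input: int
    n_eligible: int
    n_excluded: int
    wave1_prevalence_included: Optional[float]
    wave1_prevalence_excluded: Optional[float]

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


def _wave1_prevalence(records: Sequence[WomanRecord]) -> Optional[float]:
    answered = [r for r in records if r.ipv[0] is not Response.MISSING]
    if not answered:
        return None
    yes = sum(1 for r in answered if r.ipv[0] is Response.YES)
    return 100.0 * yes / len(answered)


def filter_eligible(cohort: Cohort) -> tuple[Cohort, ExclusionSummary]:
    """Split off eligible records (input order preserved) and summarise exclusions."""
    eligible = [r for r in cohort if is_eligible(r)]
    excluded = [r for r in cohort if not is_eligible(r)]
    summary = ExclusionSummary(
        n_input=len(cohort),
        n_eligible=len(eligible),
        n_excluded=len(excluded),
        wave1_prevalence_included=_wave1_prevalence(eligible),
        wave1_prevalence_excluded=_wave1_prevalence(excluded),
    )
    return Cohort(eligible, provenance=cohort.provenance), summary


def parse_pattern(pattern: str) -> tuple[Response, ...]:
    """Parse a compact pattern like ``'YNY'`` or ``'Y.Y..N'`` into six waves.

    ``.`` (or ``-``) marks a missing wave; patterns shorter than six waves are
    right-padded with MISSING.
    """
    if len(pattern) > N_WAVES:
        raise ValidationError(f"pattern longer than {N_WAVES} waves: {pattern!r}")
    out = []
    for ch in pattern.upper():
        if ch in ".-·":
            out.append(Response.MISSING)
        elif ch in _IPV_CODES:
            out.append(_IPV_CODES[ch])
        else:
            raise ValidationError(f"unknown pattern character {ch!r} in {pattern!r}")
    out.extend([Response.MISSING] * (N_WAVES - len(out)))
    return tuple(out)


def pattern_string(ipv: Sequence[Response]) -> str:
    """Inverse of :func:`parse_pattern` (MISSING rendered as ``.``)."""
    return "".join("." if r is Response.MISSING else r.value for r in ipv)
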