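"""Parsing and standardisation of raw murmuration observation records.

Citizen-science streams arrive as delimited tables with one row per
reported murmuration. Two survey-year schemas exist: year 1 recorded exact
date, location and habitat; year 2 added temperature and per-species
predator presence/activity but collected only coarse recency categories
("today" / "within the last week" / "within the last month").

Standardisation applies an ordered filter chain — historical reports,
incomplete records, zero-bird reports, zero-minute durations, and
garden/parkland feeding — with first-match attribution so per-rule removal
counts are unambiguous, followed by the murmuration-selection criteria
(flock of at least 500 birds, optionally end-witnessed, mass descent to
roost, and UK-only).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence, TextIO

from murmuration.taxa import ABSENT, ACTIVITIES, ENDINGS, PREDATOR_SPECIES, RECENCY_CATEGORIES

__all__ = [
    "MurmurationRecord",
    "FilterReport",
    "ParseIssue",
    "DEFAULT_RULES",
    "parse_records",
    "clean_records",
    "select_murmurations",
]

#: Accepted season span; 1 October is day 1 and the latest accepted report
#: falls on day 179 (a leap-year season reaching late March).
DAY_INDEX_MIN = 1
DAY_INDEX_MAX = 179

#: Reports remembered from more than a month previously are "historical".
HISTORICAL_LAG_DAYS = 31


@dataclass(frozen=True)
class MurmurationRecord:
    """One reported murmuration observation.

    ``report_lag_days`` holds an exact lag in days (year 1) or one of the
    coarse recency categories (year 2). ``predator_obs`` maps species name
    to its recorded activity; species not reported map to ``"absent"``.
    """

    record_id: str
    survey_year: int
    day_index: int
    report_lag_days: int | str
    flock_size: int
    duration_min: float
    end_seen: bool
    ending: str = "unknown"
    is_uk: bool = True
    latitude: float | None = None
    longitude: float | None = None
    settlement_class: str | None = None
    habitat: str | None = None
    temperature_c: float | None = None
    predator_obs: Mapping[str, str] = field(default_factory=dict)
    is_garden_feeding: bool = False
    complete: bool = True
    day_length_h: float | None = None

    def __post_init__(self) -> None:
        if self.survey_year not in (1, 2):
            raise ValueError(f"survey_year must be 1 or 2, got {self.survey_year}")
        if not (DAY_INDEX_MIN <= self.day_index <= DAY_INDEX_MAX):
            raise ValueError(
                f"day_index {self.day_index} outside [{DAY_INDEX_MIN}, {DAY_INDEX_MAX}]"
            )
        if isinstance(self.report_lag_days, str):
            if self.report_lag_days not in RECENCY_CATEGORIES:
                raise ValueError(f"unknown recency category {self.report_lag_days!r}")
        elif self.report_lag_days < 0:
            raise ValueError("report_lag_days must be non-negative")
        if self.flock_size < 0:
            raise ValueError("flock_size must be non-negative")
        if self.duration_min < 0:
            raise ValueError("duration_min must be non-negative")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if self.ending not in ENDINGS:
            raise ValueError(f"unknown ending {self.ending!r}")
        if self.ending != "unknown" and not self.end_seen:
            raise ValueError("a known ending requires end_seen")
        for sp, act in self.predator_obs.items():
            if sp not in PREDATOR_SPECIES and sp != "other":
                raise ValueError(f"unknown predator species {sp!r}")
            if act not in ACTIVITIES and act != ABSENT:
                raise ValueError(f"unknown activity {act!r}")

    def activity_of(self, species: str) -> str:
        """Recorded activity for *species*, ``"absent"`` if not reported."""
        return self.predator_obs.get(species, ABSENT)

    @property
    def is_historical(self) -> bool:
        """True when the sighting was remembered from more than a month before."""
        if isinstance(self.report_lag_days, str):
            return self.report_lag_days == "over_month"
        return self.report_lag_days > HISTORICAL_LAG_DAYS


@dataclass(frozen=True)
class ParseIssue:
    """A malformed input row: its 1-based row number and the reason."""

    row: int
    reason: str


@dataclass
class FilterReport:
    """Audit trail for one pass of the standardisation chain."""

    input_count: int
    removed: dict[str, int]
    removal_reason: dict[str, str]
    output_count: int

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "removed": self.removed,
                "removal_reason": self.removal_reason,
                "output_count": self.output_count,
            },
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Parsing

#: Canonical CSV column names; a schema config may remap any of them.
CANONICAL_COLUMNS = (
    "record_id",
    "survey_year",
    "day_index",
    "report_lag_days",
    "latitude",
    "longitude",
    "is_uk",
    "settlement_class",
    "habitat",
    "flock_size",
    "duration_min",
    "end_seen",
    "ending",
    "temperature_c",
    "is_garden_feeding",
    "complete",
)

MANDATORY_COLUMNS = (
    "record_id",
    "survey_year",
    "day_index",
    "flock_size",
    "duration_min",
    "end_seen",
)

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def _parse_bool(text: str, field_name: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"unparseable {field_name}")


def _parse_int(text: str, field_name: str) -> int:
    try:
        return int(text.strip())
    except ValueError:
        raise ValueError(f"unparseable {field_name}") from None


def _parse_float(text: str, field_name: str) -> float:
    try:
        return float(text.strip())
    except ValueError:
        raise ValueError(f"unparseable {field_name}") from None


def _optional(text: str | None) -> str | None:
    if text is None or text.strip() == "":
        return None
    return text.strip()


def parse_records(
    raw_table: TextIO | str,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[MurmurationRecord], list[ParseIssue]]:
    """Parse a delimited text table into records.

    Parameters
    ----------
    raw_table
        An open text stream (or a string) containing a comma-delimited,
        UTF-8 table with a header row.
    schema
        Optional mapping from canonical field name to the column name used
        in this table; unmapped fields use their canonical names.
        Per-species predator activity is read from ``predator_<species>``
        columns holding an activity label or ``absent``/empty.

    Returns
    -------
    (records, issues)
        Well-formed rows become :class:`MurmurationRecord`; malformed rows
        are reported as :class:`ParseIssue` (1-based data-row number plus
        reason) and never abort the run.

    Raises
    ------
    ValueError
        If a mandatory column is missing from the header (a configuration
        error, as opposed to a data error).
    """
    if isinstance(raw_table, str):
        raw_table = io.StringIO(raw_table)
    schema = dict(schema or {})
    colname = {f: schema.get(f, f) for f in CANONICAL_COLUMNS}

    reader = csv.DictReader(raw_table)
    header = reader.fieldnames or []
    missing = [f for f in MANDATORY_COLUMNS if colname[f] not in header]
    if missing:
        raise ValueError(f"missing mandatory columns: {', '.join(missing)}")

    predator_cols = {
        c[len("predator_"):]: c for c in header if c.startswith("predator_")
    }

    records: list[MurmurationRecord] = []
    issues: list[ParseIssue] = []
    for row_num, row in enumerate(reader, start=1):
        try:
            records.append(_row_to_record(row, colname, predator_cols))
        except ValueError as exc:
            issues.append(ParseIssue(row=row_num, reason=str(exc)))
    return records, issues


def _row_to_record(
    row: Mapping[str, str],
    colname: Mapping[str, str],
    predator_cols: Mapping[str, str],
) -> MurmurationRecord:
    def get(f: str) -> str:
        return row.get(colname[f]) or ""

    lag_raw = get("report_lag_days").strip()
    lag: int | str
    if lag_raw == "":
        lag = 0
    elif lag_raw in RECENCY_CATEGORIES:
        lag = lag_raw
    else:
        lag = _parse_int(lag_raw, "report_lag_days")

    predator_obs: dict[str, str] = {}
    for species, col in predator_cols.items():
        act = (row.get(col) or "").strip()
        if act and act != ABSENT:
            predator_obs[species] = act

    lat = _optional(get("latitude"))
    lon = _optional(get("longitude"))
    temp = _optional(get("temperature_c"))
    return MurmurationRecord(
        record_id=get("record_id").strip(),
        survey_year=_parse_int(get("survey_year"), "survey_year"),
        day_index=_parse_int(get("day_index"), "day_index"),
        report_lag_days=lag,
        flock_size=_parse_int(get("flock_size"), "flock_size"),
        duration_min=_parse_float(get("duration_min"), "duration_min"),
        end_seen=_parse_bool(get("end_seen"), "end_seen"),
        ending=_optional(get("ending")) or "unknown",
        is_uk=_parse_bool(get("is_uk") or "true", "is_uk"),
        latitude=_parse_float(lat, "latitude") if lat is not None else None,
        longitude=_parse_float(lon, "longitude") if lon is not None else None,
        settlement_class=_optional(get("settlement_class")),
        habitat=_optional(get("habitat")),
        temperature_c=_parse_float(temp, "temperature_c") if temp is not None else None,
        predator_obs=predator_obs,
        is_garden_feeding=_parse_bool(get("is_garden_feeding") or "false", "is_garden_feeding"),
        complete=_parse_bool(get("complete") or "true", "complete"),
    )


# ---------------------------------------------------------------------------
# Standardisation chain

Rule = tuple[str, Callable[[MurmurationRecord], bool]]

#: The ordered default chain. A record is attributed to the first rule it
#: violates, so per-rule counts always sum to the total removed.
DEFAULT_RULES: tuple[Rule, ...] = (
    ("historical", lambda r: r.is_historical),
    ("incomplete", lambda r: not r.complete),
    ("zero_birds", lambda r: r.flock_size == 0),
    ("zero_duration", lambda r: r.duration_min == 0),
    ("garden_feeding", lambda r: r.is_garden_feeding),
)


def clean_records(
    records: Iterable[MurmurationRecord],
    rules: Sequence[Rule] = DEFAULT_RULES,
) -> tuple[list[MurmurationRecord], FilterReport]:
    """Apply the ordered standardisation chain.

    Records are never mutated, only excluded. The returned
    :class:`FilterReport` tallies removals per rule (first matching rule
    wins) and maps each removed ``record_id`` to the rule that claimed it.
    """
    records = list(records)
    removed = {name: 0 for name, _ in rules}
    removal_reason: dict[str, str] = {}
    survivors: list[MurmurationRecord] = []
    for rec in records:
        for name, pred in rules:
            if pred(rec):
                removed[name] += 1
                removal_reason[rec.record_id] = name
                break
        else:
            survivors.append(rec)
    report = FilterReport(
        input_count=len(records),
        removed=removed,
        removal_reason=removal_reason,
        output_count=len(survivors),
    )
    return survivors, report


def select_murmurations(
    records: Iterable[MurmurationRecord],
    min_size: int = 500,
    require_end_seen: bool = False,
    require_roost_descent: bool = False,
    uk_only: bool = False,
) -> list[MurmurationRecord]:
    """Select records that qualify as true murmurations.

    The default 500-bird floor follows field estimates of the smallest
    flocks producing a definite murmuration pattern (≈430–450 birds).
    Requiring mass descent to roost distinguishes a pre-roost display from
    a flock merely relocating. Original record order is preserved.
    """
    if min_size < 0:
        raise ValueError("min_size must be non-negative")
    out = []
    for rec in records:
        if rec.flock_size < min_size:
            continue
        if require_end_seen and not rec.end_seen:
            continue
        if require_roost_descent and rec.ending != "roost_en_masse":
            continue
        if uk_only and not rec.is_uk:
            continue
        out.append(rec)
    return out
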