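"""Colorectal-audit quality indicators 2b (short waiting time) and 8
(postoperative complication rate) as pure cohort-rows -> aggregate functions.

Both indicators follow the audit's published structure — a numerator /
denominator pair over the resection population of one tumor localization,
excluding patients referred from elsewhere — with the combination rules the
registry itself does not publish made explicit here:

* Waiting time is the whole-day difference between the diagnosis date and
  the *first* therapy date (the earlier of neoadjuvant-therapy start and
  surgery); "short" means strictly fewer than 35 days (< 5 weeks).
* The complication rate is crude: case-mix variables travel with the
  cohort but no adjustment is applied.
* Rows missing the diagnosis date are dropped from the waiting-time
  denominator, with a logged count.

Results are exact: integer counts plus the exact ratio.  Display rounding
(integer percentages, 3-decimal rates) belongs to reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

from .synthetic_ehr import PatientRecord, WAITING_THRESHOLD_DAYS

logger = logging.getLogger(__name__)

INDICATOR_IDS = ("qi2b", "qi8")


@dataclass(frozen=True)
class IndicatorSpec:
    indicator_id: str  # "qi2b" | "qi8"
    localization: str  # "colon" | "rectum"
    waiting_threshold_days: int = WAITING_THRESHOLD_DAYS  # qi2b only
    exclude_referred: bool = True

    def __post_init__(self) -> None:
        if self.indicator_id not in INDICATOR_IDS:
            raise ValueError(f"unknown indicator_id {self.indicator_id!r}")
        if self.localization not in ("colon", "rectum"):
            raise ValueError(f"unknown localization {self.localization!r}")
        if self.waiting_threshold_days <= 0:
            raise ValueError("waiting_threshold_days must be positive")

    def to_json(self) -> dict:
        return {
            "indicator_id": self.indicator_id,
            "localization": self.localization,
            "waiting_threshold_days": self.waiting_threshold_days,
            "exclude_referred": self.exclude_referred,
        }

    @classmethod
    def from_json(cls, raw: Mapping) -> "IndicatorSpec":
        return cls(
            indicator_id=raw["indicator_id"],
            localization=raw["localization"],
            waiting_threshold_days=raw.get("waiting_threshold_days", WAITING_THRESHOLD_DAYS),
            exclude_referred=raw.get("exclude_referred", True),
        )


@dataclass(frozen=True)
class LocalResult:
    """Aggregate-only indicator output for one center.

    ``ratio`` is ``None`` when the denominator is zero (undefined) or the
    result is suppressed; it otherwise equals numerator/denominator exactly.
    """

    center_id: str
    indicator_id: str
    denominator: Optional[int]
    numerator: Optional[int]
    ratio: Optional[float]
    suppressed: bool = False

    def __post_init__(self) -> None:
        if not self.suppressed:
            if self.numerator is None or self.denominator is None:
                raise ValueError("unsuppressed result needs integer counts")
            if not 0 <= self.numerator <= self.denominator:
                raise ValueError("need 0 <= numerator <= denominator")
            if self.denominator > 0 and self.ratio != self.numerator / self.denominator:
                raise ValueError("ratio must equal numerator/denominator exactly")

    def to_payload(self) -> dict:
        return {
            "center_id": self.center_id,
            "indicator_id": self.indicator_id,
            "denominator": self.denominator,
            "numerator": self.numerator,
            "ratio": self.ratio,
            "suppressed": self.suppressed,
        }

    @classmethod
    def from_payload(cls, payload: Mapping) -> "LocalResult":
        return cls(
            center_id=payload["center_id"],
            indicator_id=payload["indicator_id"],
            denominator=payload["denominator"],
            numerator=payload["numerator"],
            ratio=payload["ratio"],
            suppressed=payload["suppressed"],
        )


# --- row model ------------------------------------------------------------
#
# Indicator functions consume plain mappings with the canonical keys below,
# as produced either by the shipped SPARQL retrieval queries (variable names
# match) or by `rows_from_records` for direct, station-free computation.

ROW_KEYS_QI2B = (
    "localization",
    "referred",
    "date_of_diagnosis",
    "date_neoadjuvant_start",
    "date_of_surgery",
)
ROW_KEYS_QI8 = ("localization", "referred", "postop_complication")


def rows_from_records(records: Iterable[PatientRecord]) -> list[dict]:
    """Adapter for computing indicators straight off a flat table."""
    return [
        {
            "localization": r.tumor_localization,
            "referred": r.referred,
            "date_of_diagnosis": r.date_of_diagnosis,
            "date_neoadjuvant_start": r.date_neoadjuvant_start,
            "date_of_surgery": r.date_of_surgery,
            "postop_complication": r.postop_complication,
        }
        for r in records
    ]


def first_therapy_date(
    date_neoadjuvant_start: Optional[date], date_of_surgery: date
) -> date:
    """The start of therapy: neoadjuvant start if it precedes surgery."""
    if date_neoadjuvant_start is None:
        return date_of_surgery
    return min(date_neoadjuvant_start, date_of_surgery)


def _in_cohort(row: Mapping, spec: IndicatorSpec) -> bool:
    if row.get("localization") != spec.localization:
        return False
    if spec.exclude_referred and row.get("referred"):
        return False
    return True


def _result(center_id: str, spec: IndicatorSpec, denominator: int, numerator: int) -> LocalResult:
    if denominator == 0:
        logger.warning(
            "%s/%s: empty cohort, ratio undefined", center_id, spec.indicator_id
        )
        return LocalResult(center_id, spec.indicator_id, 0, 0, None)
    return LocalResult(
        center_id, spec.indicator_id, denominator, numerator, numerator / denominator
    )


def qi2b(rows: Sequence[Mapping], spec: IndicatorSpec, center_id: str = "") -> LocalResult:
    """Short-waiting-time indicator: share of the (non-referred) cohort with
    strictly fewer than ``waiting_threshold_days`` whole days between the
    diagnosis date and the first therapy date."""
    cohort = [r for r in rows if _in_cohort(r, spec)]
    with_diagnosis = [r for r in cohort if r.get("date_of_diagnosis") is not None]
    dropped = len(cohort) - len(with_diagnosis)
    if dropped:
        logger.warning(
            "%s/qi2b: %d record(s) without diagnosis date excluded from denominator",
            center_id,
            dropped,
        )
    numerator = 0
    for r in with_diagnosis:
        therapy = first_therapy_date(r.get("date_neoadjuvant_start"), r["date_of_surgery"])
        wait_days = (therapy - r["date_of_diagnosis"]).days
        if wait_days < spec.waiting_threshold_days:
            numerator += 1
    return _result(center_id, spec, len(with_diagnosis), numerator)


def qi8(rows: Sequence[Mapping], spec: IndicatorSpec, center_id: str = "") -> LocalResult:
    """Crude postoperative complication rate over the resection cohort."""
    cohort = [r for r in rows if _in_cohort(r, spec)]
    numerator = sum(1 for r in cohort if r.get("postop_complication"))
    return _result(center_id, spec, len(cohort), numerator)


def compute(rows: Sequence[Mapping], spec: IndicatorSpec, center_id: str = "") -> LocalResult:
    if spec.indicator_id == "qi2b":
        return qi2b(rows, spec, center_id)
    return qi8(rows, spec, center_id)


def format_percentage(ratio: float) -> str:
    """Audit display convention: percentages as integers."""
    return f"{round(ratio * 100):d}"


def format_rate(ratio: float) -> str:
    """Audit display convention: rates to three decimals."""
    return f"{ratio:.3f}"
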