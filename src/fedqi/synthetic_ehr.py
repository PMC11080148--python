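"""Synthetic per-center colorectal-surgery cohorts.

Generates flat patient tables with the variable set a national colorectal
audit uses for its waiting-time and complication indicators: tumor
localization, referral status, diagnosis / neoadjuvant / surgery dates,
resection type, and the case-mix variables (age, BMI, Charlson score, ASA
class, preoperative tumor complications) plus the postoperative
complication outcome.

Two sampling modes are available:

* **Bernoulli mode** — every marginal is an independent draw from its
  configured probability or distribution spec.
* **Quota mode** — per-localization (denominator, numerator) pairs are hit
  *exactly* via shuffled assignment: for the colon cohort the numerator is
  the count of patients with a short (< 35 whole days) diagnosis-to-therapy
  wait, for the rectum cohort it is the count with a postoperative
  complication.  Records beyond the quota denominators are generated as
  referred patients so they fall outside the default indicator cohorts.

All randomness flows through a single ``numpy`` generator seeded from the
config; identical (config, seed) gives byte-identical CSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

WAITING_THRESHOLD_DAYS = 35  # "< 5 weeks" between diagnosis and first therapy

RESECTION_TYPES = (
    "low_anterior_resection",
    "abdominoperineal_resection",
    "sigmoid_resection",
    "right_hemicolectomy",
)

CSV_COLUMNS = [
    "patient_id",
    "hospital_id",
    "tumor_localization",
    "referred",
    "date_of_diagnosis",
    "date_neoadjuvant_start",
    "date_of_surgery",
    "resection_type",
    "age",
    "bmi",
    "charlson_score",
    "asa_class",
    "preop_tumor_complication",
    "postop_complication",
]

_BOOL_COLUMNS = {"referred", "preop_tumor_complication", "postop_complication"}
_DATE_COLUMNS = {"date_of_diagnosis", "date_neoadjuvant_start", "date_of_surgery"}

_BASE_DIAGNOSIS_DATE = date(2021, 1, 1)


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


class SchemaError(ValueError):
    """Malformed flat-table file; message names the row/column at fault."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    hospital_id: str
    tumor_localization: str  # "colon" | "rectum"
    referred: bool
    date_of_diagnosis: date
    date_neoadjuvant_start: Optional[date]
    date_of_surgery: date
    resection_type: str
    age: int
    bmi: float
    charlson_score: int
    asa_class: int
    preop_tumor_complication: bool
    postop_complication: bool

    def __post_init__(self) -> None:
        if self.tumor_localization not in ("colon", "rectum"):
            raise ConfigError(
                f"tumor_localization must be colon/rectum, got {self.tumor_localization!r}"
            )
        if self.date_of_diagnosis > self.date_of_surgery:
            raise ConfigError("date_of_diagnosis must be on or before date_of_surgery")
        if self.date_neoadjuvant_start is not None and not (
            self.date_of_diagnosis <= self.date_neoadjuvant_start <= self.date_of_surgery
        ):
            raise ConfigError("date_neoadjuvant_start must lie between diagnosis and surgery")
        if not 1 <= self.asa_class <= 5:
            raise ConfigError(f"asa_class must be in 1..5, got {self.asa_class}")
        if self.age < 0:
            raise ConfigError("age must be non-negative")
        if self.bmi <= 0:
            raise ConfigError("bmi must be positive")
        if self.charlson_score < 0:
            raise ConfigError("charlson_score must be non-negative")


@dataclass(frozen=True)
class FlatTable:
    center_id: str
    records: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SchemaError("patient_id values must be unique within a table")
        for r in self.records:
            if r.hospital_id != self.center_id:
                raise SchemaError(
                    f"record {r.patient_id} carries hospital_id {r.hospital_id!r},"
                    f" expected {self.center_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "hospital_id": r.hospital_id,
                    "tumor_localization": r.tumor_localization,
                    "referred": "yes" if r.referred else "no",
                    "date_of_diagnosis": r.date_of_diagnosis.isoformat(),
                    "date_neoadjuvant_start": (
                        r.date_neoadjuvant_start.isoformat()
                        if r.date_neoadjuvant_start
                        else ""
                    ),
                    "date_of_surgery": r.date_of_surgery.isoformat(),
                    "resection_type": r.resection_type,
                    "age": r.age,
                    "bmi": f"{r.bmi:.1f}",
                    "charlson_score": r.charlson_score,
                    "asa_class": r.asa_class,
                    "preop_tumor_complication": "yes" if r.preop_tumor_complication else "no",
                    "postop_complication": "yes" if r.postop_complication else "no",
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


# --- distribution specs ---------------------------------------------------

def _sample_distribution(spec: dict, rng: np.random.Generator, field_name: str):
    """Draw one value from a {"name": ..., params} distribution spec."""
    try:
        name = spec["name"]
    except (TypeError, KeyError):
        raise ConfigError(f"{field_name}: distribution spec needs a 'name'") from None
    try:
        if name == "normal":
            lo = spec.get("low", -np.inf)
            hi = spec.get("high", np.inf)
            for _ in range(1000):
                v = rng.normal(spec["mean"], spec["sd"])
                if lo <= v <= hi:
                    return v
            raise ConfigError(f"{field_name}: truncation bounds reject all samples")
        if name == "lognormal":
            lo = spec.get("low", 0.0)
            hi = spec.get("high", np.inf)
            for _ in range(1000):
                v = rng.lognormal(spec["mean_log"], spec["sd_log"])
                if lo <= v <= hi:
                    return v
            raise ConfigError(f"{field_name}: truncation bounds reject all samples")
        if name == "poisson":
            hi = spec.get("high")
            v = int(rng.poisson(spec["lam"]))
            return min(v, hi) if hi is not None else v
        if name == "uniform_int":
            return int(rng.integers(spec["low"], spec["high"] + 1))
        if name == "categorical":
            values = list(spec["values"])
            probs = [spec["values"][k] for k in values]
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"{field_name}: categorical probabilities must sum to 1")
            idx = rng.choice(len(values), p=probs)
            return values[idx]
        if name == "bernoulli":
            p = spec["p"]
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{field_name}: p must be in [0, 1]")
            return bool(rng.random() < p)
        if name == "constant":
            return spec["value"]
    except KeyError as exc:
        raise ConfigError(f"{field_name}: missing distribution parameter {exc}") from None
    raise ConfigError(f"{field_name}: unknown distribution {name!r}")


_DEFAULT_DISTRIBUTIONS = {
    # Fixture distributions for a plausible elderly surgical cohort; the
    # indicator arithmetic never depends on them.
    "age": {"name": "normal", "mean": 68.0, "sd": 11.0, "low": 18, "high": 95},
    "bmi": {"name": "lognormal", "mean_log": 3.26, "sd_log": 0.15, "low": 15, "high": 50},
    "charlson": {"name": "poisson", "lam": 1.2, "high": 12},
    "asa": {
        "name": "categorical",
        "values": {"1": 0.12, "2": 0.55, "3": 0.28, "4": 0.045, "5": 0.005},
    },
    "preop_complication": {"name": "bernoulli", "p": 0.25},
    "waiting_time_days": {"name": "uniform_int", "low": 7, "high": 62},
}


@dataclass(frozen=True)
class GeneratorConfig:
    center_id: str
    n_patients: int
    seed: int
    rectum_fraction: float = 0.45
    referred_fraction: float = 0.10
    neoadjuvant_fraction: float = 0.30
    complication_prob: float = 0.30
    short_wait_fraction: Optional[float] = None
    waiting_time_days: dict = field(
        default_factory=lambda: dict(_DEFAULT_DISTRIBUTIONS["waiting_time_days"])
    )
    quota_counts: Optional[dict[str, tuple[int, int]]] = None
    age: dict = field(default_factory=lambda: dict(_DEFAULT_DISTRIBUTIONS["age"]))
    bmi: dict = field(default_factory=lambda: dict(_DEFAULT_DISTRIBUTIONS["bmi"]))
    charlson: dict = field(default_factory=lambda: dict(_DEFAULT_DISTRIBUTIONS["charlson"]))
    asa: dict = field(default_factory=lambda: dict(_DEFAULT_DISTRIBUTIONS["asa"]))
    preop_complication: dict = field(
        default_factory=lambda: dict(_DEFAULT_DISTRIBUTIONS["preop_complication"])
    )

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        for name in (
            "rectum_fraction",
            "referred_fraction",
            "neoadjuvant_fraction",
            "complication_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        if self.short_wait_fraction is not None and not 0.0 <= self.short_wait_fraction <= 1.0:
            raise ConfigError(
                f"short_wait_fraction must be a probability in [0, 1], got {self.short_wait_fraction}"
            )
        if self.quota_counts is not None:
            total = 0
            for loc, pair in self.quota_counts.items():
                if loc not in ("colon", "rectum"):
                    raise ConfigError(f"quota_counts: unknown localization {loc!r}")
                denom, num = pair
                if not (0 <= num <= denom):
                    raise ConfigError(
                        f"quota_counts[{loc}]: numerator {num} must be in [0, denominator {denom}]"
                    )
                total += denom
            if total > self.n_patients:
                raise ConfigError(
                    f"quota_counts: denominators sum to {total} > n_patients {self.n_patients}"
                )

    @classmethod
    def from_json(cls, source: Union[str, Path, dict]) -> "GeneratorConfig":
        if isinstance(source, (str, Path)):
            raw = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            raw = dict(source)
        if "quota_counts" in raw and raw["quota_counts"] is not None:
            raw["quota_counts"] = {
                loc: (int(pair[0]), int(pair[1])) for loc, pair in raw["quota_counts"].items()
            }
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        missing = {"center_id", "n_patients", "seed"} - set(raw)
        if missing:
            raise ConfigError(f"missing required config fields: {sorted(missing)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def default_config_path() -> Path:
    return Path(str(resources.files("fedqi").joinpath("data/default_generator_config.json")))


# --- generation -----------------------------------------------------------

def _make_record(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    index: int,
    localization: str,
    referred: bool,
    waiting_days: int,
    postop_complication: bool,
) -> PatientRecord:
    diagnosis = _BASE_DIAGNOSIS_DATE + timedelta(days=int(rng.integers(0, 365)))
    neoadjuvant: Optional[date] = None
    if rng.random() < cfg.neoadjuvant_fraction:
        neoadjuvant = diagnosis + timedelta(days=waiting_days)
        surgery = neoadjuvant + timedelta(days=int(rng.integers(14, 61)))
    else:
        surgery = diagnosis + timedelta(days=waiting_days)
    if localization == "rectum":
        resection = RESECTION_TYPES[int(rng.integers(0, 2))]
    else:
        resection = RESECTION_TYPES[2 + int(rng.integers(0, 2))]
    return PatientRecord(
        patient_id=f"{cfg.center_id}-{index:05d}",
        hospital_id=cfg.center_id,
        tumor_localization=localization,
        referred=referred,
        date_of_diagnosis=diagnosis,
        date_neoadjuvant_start=neoadjuvant,
        date_of_surgery=surgery,
        resection_type=resection,
        age=int(round(_sample_distribution(cfg.age, rng, "age"))),
        bmi=round(float(_sample_distribution(cfg.bmi, rng, "bmi")), 1),
        charlson_score=int(_sample_distribution(cfg.charlson, rng, "charlson")),
        asa_class=int(_sample_distribution(cfg.asa, rng, "asa")),
        preop_tumor_complication=bool(
            _sample_distribution(cfg.preop_complication, rng, "preop_complication")
        ),
        postop_complication=postop_complication,
    )


def _sample_wait(cfg: GeneratorConfig, rng: np.random.Generator, short: Optional[bool]) -> int:
    """Waiting time in whole days; ``short`` forces the < 35-day side."""
    if short is True:
        return int(rng.integers(1, WAITING_THRESHOLD_DAYS))
    if short is False:
        return int(rng.integers(WAITING_THRESHOLD_DAYS, 2 * WAITING_THRESHOLD_DAYS + 21))
    w = int(round(_sample_distribution(cfg.waiting_time_days, rng, "waiting_time_days")))
    return max(w, 0)


def generate_center(config: GeneratorConfig) -> FlatTable:
    """Generate one center's flat table deterministically from (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    index = 0

    if config.quota_counts is not None:
        for loc in sorted(config.quota_counts):
            denom, num = config.quota_counts[loc]
            event = np.zeros(denom, dtype=bool)
            event[rng.permutation(denom)[:num]] = True  # shuffled exact assignment
            for has_event in event:
                if loc == "colon":
                    wait = _sample_wait(config, rng, short=bool(has_event))
                    complication = bool(rng.random() < config.complication_prob)
                else:
                    wait = _sample_wait(
                        config,
                        rng,
                        short=(
                            bool(rng.random() < config.short_wait_fraction)
                            if config.short_wait_fraction is not None
                            else None
                        ),
                    )
                    complication = bool(has_event)
                records.append(
                    _make_record(config, rng, index, loc, False, wait, complication)
                )
                index += 1
        # Filler beyond the quota denominators: referred patients, outside
        # the (non-referred) indicator cohorts by construction.
        for _ in range(config.n_patients - index):
            loc = "rectum" if rng.random() < config.rectum_fraction else "colon"
            wait = _sample_wait(config, rng, short=None)
            complication = bool(rng.random() < config.complication_prob)
            records.append(_make_record(config, rng, index, loc, True, wait, complication))
            index += 1
    else:
        for _ in range(config.n_patients):
            loc = "rectum" if rng.random() < config.rectum_fraction else "colon"
            referred = bool(rng.random() < config.referred_fraction)
            short = (
                bool(rng.random() < config.short_wait_fraction)
                if config.short_wait_fraction is not None
                else None
            )
            wait = _sample_wait(config, rng, short=short)
            complication = bool(rng.random() < config.complication_prob)
            records.append(_make_record(config, rng, index, loc, referred, wait, complication))
            index += 1

    return FlatTable(center_id=config.center_id, records=tuple(records))


# --- CSV I/O --------------------------------------------------------------

def write_flat_table(table: FlatTable, path: Union[str, Path]) -> None:
    """UTF-8 comma-delimited CSV; ISO-8601 dates; yes/no booleans; '' = missing."""
    table.to_dataframe().to_csv(path, index=False, encoding="utf-8")


def _parse_bool(raw: str, row: int, column: str) -> bool:
    if raw == "yes":
        return True
    if raw == "no":
        return False
    raise SchemaError(f"row {row}, column {column!r}: expected yes/no, got {raw!r}")


def _parse_date(raw: str, row: int, column: str) -> date:
    try:
        return date.fromisoformat(raw)
    except ValueError:
        raise SchemaError(
            f"row {row}, column {column!r}: expected ISO-8601 date, got {raw!r}"
        ) from None


def read_flat_table(path: Union[str, Path]) -> FlatTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    records = []
    center_id: Optional[str] = None
    for i, row in enumerate(df.itertuples(index=False)):
        cells = dict(zip(df.columns, row))
        try:
            rec = PatientRecord(
                patient_id=cells["patient_id"],
                hospital_id=cells["hospital_id"],
                tumor_localization=cells["tumor_localization"],
                referred=_parse_bool(cells["referred"], i, "referred"),
                date_of_diagnosis=_parse_date(cells["date_of_diagnosis"], i, "date_of_diagnosis"),
                date_neoadjuvant_start=(
                    _parse_date(cells["date_neoadjuvant_start"], i, "date_neoadjuvant_start")
                    if cells["date_neoadjuvant_start"]
                    else None
                ),
                date_of_surgery=_parse_date(cells["date_of_surgery"], i, "date_of_surgery"),
                resection_type=cells["resection_type"],
                age=_parse_int(cells["age"], i, "age"),
                bmi=_parse_float(cells["bmi"], i, "bmi"),
                charlson_score=_parse_int(cells["charlson_score"], i, "charlson_score"),
                asa_class=_parse_int(cells["asa_class"], i, "asa_class"),
                preop_tumor_complication=_parse_bool(
                    cells["preop_tumor_complication"], i, "preop_tumor_complication"
                ),
                postop_complication=_parse_bool(cells["postop_complication"], i, "postop_complication"),
            )
        except ConfigError as exc:
            raise SchemaError(f"row {i}: {exc}") from None
        records.append(rec)
        center_id = rec.hospital_id if center_id is None else center_id
    return FlatTable(center_id=center_id or "", records=tuple(records))


def _parse_int(raw: str, row: int, column: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise SchemaError(f"row {row}, column {column!r}: expected integer, got {raw!r}") from None


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(f"row {row}, column {column!r}: expected number, got {raw!r}") from None
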