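"""Trains, the local/master algorithm split, and aggregate-only auditing.

A *train* bundles a cohort-retrieval SPARQL query with the indicator
parameters (and nothing else — it carries no data).  Dispatch is
in-process but crosses a hard interface boundary: the orchestrator hands a
train to each station, the station executes the query and the local
algorithm internally, and the only thing that travels back is an aggregate
payload which must pass a closed-world schema audit
(:func:`validate_payload`) before it is accepted.

The master step combines the per-center aggregates: the cross-center mean
ratio (unweighted by default; a pooled numerator/denominator mean is
available), and the two derived quantities the comparison plots use —
expected events (mean ratio x center denominator) and each center's rate
relative to the mean.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

from ._sparql import SparqlParseError
from .indicators import IndicatorSpec, LocalResult, compute
from .station import FairStation, execute_sparql

logger = logging.getLogger(__name__)

PAYLOAD_FIELDS = {
    "center_id": str,
    "indicator_id": str,
    "denominator": int,
    "numerator": int,
    "ratio": float,
    "suppressed": bool,
}
_NULLABLE = {"denominator", "numerator", "ratio"}


class FederatedError(RuntimeError):
    pass


@dataclass(frozen=True)
class Train:
    """Query + algorithm parameters; never data.

    ``local_algorithm`` defaults to the indicator computation; it exists so
    tests can model an adversarial train whose payload must be rejected by
    the schema audit.
    """

    train_id: str
    sparql_query: str
    indicator_spec: IndicatorSpec
    local_algorithm: Optional[Callable[[list[dict], IndicatorSpec, str], Mapping]] = field(
        default=None, compare=False
    )

    @classmethod
    def from_json(cls, source: Union[str, Path, dict]) -> "Train":
        if isinstance(source, (str, Path)):
            base = Path(source).parent
            raw = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            base, raw = Path("."), dict(source)
        if "query_file" in raw:
            query = (base / raw["query_file"]).read_text(encoding="utf-8")
        else:
            query = raw["sparql_query"]
        return cls(
            train_id=raw["train_id"],
            sparql_query=query,
            indicator_spec=IndicatorSpec.from_json(raw["indicator_spec"]),
        )


def default_query(indicator_id: str) -> str:
    """The shipped cohort-retrieval query for an indicator (one file each)."""
    if indicator_id not in ("qi2b", "qi8"):
        raise FederatedError(f"no shipped query for indicator {indicator_id!r}")
    return resources.files("fedqi").joinpath(f"data/queries/{indicator_id}.rq").read_text(
        encoding="utf-8"
    )


def default_train(indicator_id: str, localization: Optional[str] = None, **spec_kwargs) -> Train:
    """A ready-to-dispatch train for one indicator.

    The default localizations reproduce the audit's published per-center
    table: waiting time over the colon population, complications over the
    rectum population.
    """
    if localization is None:
        localization = "colon" if indicator_id == "qi2b" else "rectum"
    spec = IndicatorSpec(indicator_id=indicator_id, localization=localization, **spec_kwargs)
    return Train(
        train_id=f"{indicator_id}-{localization}",
        sparql_query=default_query(indicator_id),
        indicator_spec=spec,
    )


def execute_train_locally(station: FairStation, train: Train) -> dict:
    """The local algorithm: runs *inside* the station boundary.

    Retrieves the cohort with the train's query, computes the indicator,
    applies the station's suppression policy, and stages an aggregate-only
    payload.  A query failure yields an error payload, never partial data.
    """
    try:
        result = execute_sparql(station, train.sparql_query)
        rows = result.to_dicts()
        algorithm = train.local_algorithm
        if algorithm is None:
            local = compute(rows, train.indicator_spec, station.center_id).to_payload()
        else:
            local = dict(algorithm(rows, train.indicator_spec, station.center_id))
    except SparqlParseError as exc:
        return {"center_id": station.center_id, "error": str(exc)}
    return station._apply_policy(local)


def run_train(station: FairStation, train: Train) -> LocalResult:
    """Dispatch one train to one station and audit the returned payload."""
    t0 = time.perf_counter()
    station.accept_train(train)
    payload = station.return_payload()
    elapsed = time.perf_counter() - t0
    if "error" in payload:
        raise FederatedError(
            f"train {train.train_id!r} failed at station {station.center_id!r}:"
            f" {payload['error']}"
        )
    violations = validate_payload(payload)
    if violations:
        raise FederatedError(
            f"station {station.center_id!r} returned a non-conforming payload: "
            + "; ".join(violations)
        )
    logger.info("station %s: train %s done in %.3fs", station.center_id, train.train_id, elapsed)
    return LocalResult.from_payload(payload)


def validate_payload(payload: Mapping) -> list[str]:
    """Closed-world audit of a candidate train output.

    Returns an empty list iff the payload carries exactly the aggregate
    result fields with conforming types and count invariants.  Unknown
    fields — the channel record-level data would have to use — are
    violations, as is any numerator exceeding its denominator.
    """
    violations: list[str] = []
    if not isinstance(payload, Mapping):
        return ["payload is not a mapping"]
    for name in payload:
        if name not in PAYLOAD_FIELDS:
            violations.append(f"unknown field {name!r}")
    for name, typ in PAYLOAD_FIELDS.items():
        if name not in payload:
            violations.append(f"missing field {name!r}")
            continue
        value = payload[name]
        if value is None:
            if name not in _NULLABLE:
                violations.append(f"field {name!r} must not be null")
            continue
        if typ is float:
            ok = isinstance(value, (int, float)) and not isinstance(value, bool)
        elif typ is int:
            ok = isinstance(value, int) and not isinstance(value, bool)
        else:
            ok = isinstance(value, typ)
        if not ok:
            violations.append(f"field {name!r} has wrong type {type(value).__name__}")
    if violations:
        return violations
    num, den, ratio = payload["numerator"], payload["denominator"], payload["ratio"]
    if payload["suppressed"]:
        if any(v is not None for v in (num, den, ratio)):
            violations.append("suppressed payload must null its counts")
        return violations
    if num is None or den is None:
        violations.append("unsuppressed payload needs integer counts")
        return violations
    if num < 0 or den < 0:
        violations.append("counts must be non-negative")
    if num > den:
        violations.append(f"numerator {num} exceeds denominator {den}")
    if den > 0 and (ratio is None or ratio != num / den):
        violations.append("ratio must equal numerator/denominator")
    if den == 0 and ratio is not None:
        violations.append("ratio must be null when denominator is 0")
    return violations


@dataclass(frozen=True)
class GlobalResult:
    indicator_id: str
    local_results: tuple[LocalResult, ...]
    mean_ratio: float
    per_center_expected_events: dict[str, float]
    per_center_rate_of_mean: dict[str, float]
    mean_mode: str = "unweighted"

    def to_json(self) -> dict:
        return {
            "indicator_id": self.indicator_id,
            "mean_mode": self.mean_mode,
            "mean_ratio": self.mean_ratio,
            "local_results": [lr.to_payload() for lr in self.local_results],
            "per_center_expected_events": self.per_center_expected_events,
            "per_center_rate_of_mean": self.per_center_rate_of_mean,
        }

    @classmethod
    def from_json(cls, raw: Mapping) -> "GlobalResult":
        return cls(
            indicator_id=raw["indicator_id"],
            local_results=tuple(LocalResult.from_payload(p) for p in raw["local_results"]),
            mean_ratio=raw["mean_ratio"],
            per_center_expected_events=dict(raw["per_center_expected_events"]),
            per_center_rate_of_mean=dict(raw["per_center_rate_of_mean"]),
            mean_mode=raw.get("mean_mode", "unweighted"),
        )


def run_federated(
    stations: Sequence[FairStation], train: Train, mean_mode: str = "unweighted"
) -> GlobalResult:
    """Master algorithm: dispatch to every station, combine the aggregates.

    ``mean_mode`` "unweighted" averages the per-center ratios (the
    benchmark-style reading of a cross-center mean line); "pooled" divides
    summed numerators by summed denominators.
    """
    if not stations:
        raise FederatedError("need at least one station")
    if mean_mode not in ("unweighted", "pooled"):
        raise FederatedError(f"unknown mean_mode {mean_mode!r}")
    locals_: list[LocalResult] = [run_train(s, train) for s in stations]
    defined = [lr for lr in locals_ if lr.ratio is not None]
    skipped = [lr.center_id for lr in locals_ if lr.ratio is None]
    if skipped:
        logger.info("centers excluded from the mean (suppressed/empty): %s", skipped)
    if not defined:
        raise FederatedError("no computable centers")
    if mean_mode == "unweighted":
        mean_ratio = sum(lr.ratio for lr in defined) / len(defined)
    else:
        mean_ratio = sum(lr.numerator for lr in defined) / sum(lr.denominator for lr in defined)
    expected = {
        lr.center_id: mean_ratio * lr.denominator for lr in defined
    }
    rate_of_mean = {
        lr.center_id: (lr.ratio / mean_ratio if mean_ratio > 0 else float("nan"))
        for lr in defined
    }
    return GlobalResult(
        indicator_id=train.indicator_spec.indicator_id,
        local_results=tuple(locals_),
        mean_ratio=mean_ratio,
        per_center_expected_events=expected,
        per_center_rate_of_mean=rate_of_mean,
        mean_mode=mean_mode,
    )
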