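"""FAIR data stations: query-only hosts for a center's patient graph.

A station wraps an RDF graph behind a deliberately narrow surface.  The
orchestrator can do exactly two things with it — hand it a train
(`accept_train`) and collect the resulting aggregate payload
(`return_payload`).  SPARQL execution happens *inside* the station
boundary on behalf of a visiting train; no method exposes the graph, a
record, or row-level query results to the outside.

Result typing: before the local algorithm runs, literal bindings are
coerced to native Python values (``datetime.date``, ``bool``, ``int``,
``float``, ``str``) so indicator code never touches serialization detail.
Concept IRIs are resolved to their labels when the query retrieves the
label; otherwise they surface as IRI strings.

An optional minimum cell size suppresses small aggregates: when enabled
and either count falls below the threshold, the payload carries only the
suppressed marker.  The default is 0 (off) so that small-center results
remain exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, TYPE_CHECKING

from ._rdf import Graph, IRI, Literal
from ._sparql import QueryResult, evaluate

if TYPE_CHECKING:  # pragma: no cover
    from .federated import Train


@dataclass(frozen=True)
class AccessPolicy:
    """Aggregate-only output policy; ``min_cell_size`` 0 disables suppression."""

    min_cell_size: int = 0

    def __post_init__(self) -> None:
        if self.min_cell_size < 0:
            raise ValueError("min_cell_size must be non-negative")


def _coerce(term):
    if term is None:
        return None
    if isinstance(term, Literal):
        return term.to_python()
    if isinstance(term, IRI):
        return term.value
    return term


class FairStation:
    """One center's FAIR endpoint plus train execution environment."""

    __slots__ = ("_center_id", "_graph", "_policy", "_payload")

    def __init__(self, graph: Graph, center_id: str, policy: Optional[AccessPolicy] = None):
        self._center_id = center_id
        self._graph = graph
        self._policy = policy or AccessPolicy()
        self._payload: Optional[dict] = None

    @property
    def center_id(self) -> str:
        return self._center_id

    def accept_train(self, train: "Train") -> None:
        """Run a train inside the station; stage its aggregate payload."""
        from .federated import execute_train_locally

        self._payload = execute_train_locally(self, train)

    def return_payload(self) -> dict:
        """Release the staged aggregate payload (and only that)."""
        if self._payload is None:
            raise RuntimeError(f"station {self._center_id!r} has no staged payload")
        payload, self._payload = self._payload, None
        return payload

    # Internal boundary: callable by a train executing inside the station,
    # never part of the surface offered to the orchestrator.
    def _execute_sparql(self, query: str) -> QueryResult:
        result = evaluate(self._graph, query)
        rows = [tuple(_coerce(v) for v in row) for row in result.rows]
        return QueryResult(result.variable_names, rows)

    def _apply_policy(self, payload: dict) -> dict:
        m = self._policy.min_cell_size
        if m > 0:
            num = payload.get("numerator")
            den = payload.get("denominator")
            if (den is not None and den < m) or (num is not None and num < m):
                return {
                    "center_id": payload["center_id"],
                    "indicator_id": payload["indicator_id"],
                    "denominator": None,
                    "numerator": None,
                    "ratio": None,
                    "suppressed": True,
                }
        return payload


def host_station(
    graph: Graph, center_id: str, policy: Optional[AccessPolicy] = None
) -> FairStation:
    """Stand up a station over an already-FAIRified graph."""
    return FairStation(graph, center_id, policy)


def execute_sparql(station: FairStation, query: str) -> QueryResult:
    """Station-internal SPARQL execution (what a visiting train calls).

    This is part of the *inside* of the station boundary: results may be
    row-level and must never be forwarded beyond the station.  The
    orchestrator-facing surface is ``accept_train`` / ``return_payload``.
    """
    return station._execute_sparql(query)
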