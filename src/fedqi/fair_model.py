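"""FAIRification: flat patient tables -> RDF graphs with terminology anchors.

The graph schema is a minimal star: one subject IRI per patient
(``{base}patient/{center}/{patient_id}``), one project-namespace predicate
per table column, typed literals for dates/booleans/numbers, and concept
IRIs for coded values (tumor localization, resection type).  Semantic
anchoring to a clinical terminology (SNOMED CT) lives in the editable
mapping file, not in code: each predicate and each concept carries an
annotation triple with its terminology code.  The shipped default mapping
uses placeholder-but-plausible codes and is configuration, not a claim.

Missing optional cells produce no triple at all — no nulls, no blank nodes.
A single dataset-level provenance triple records the originating center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from ._rdf import (
    RDF_TYPE,
    RDFS_LABEL,
    XSD_BOOLEAN,
    XSD_DATE,
    XSD_DECIMAL,
    XSD_INTEGER,
    XSD_STRING,
    Graph,
    IRI,
    Literal,
    Term,
)
from .synthetic_ehr import CSV_COLUMNS, FlatTable, PatientRecord

DEFAULT_BASE_NAMESPACE = "https://w3id.org/fedqi/"

_DATATYPE_TO_XSD = {
    "date": XSD_DATE,
    "boolean": XSD_BOOLEAN,
    "integer": XSD_INTEGER,
    "decimal": XSD_DECIMAL,
}


class MappingError(ValueError):
    """Invalid ontology mapping or a cell that the mapping cannot code."""


@dataclass(frozen=True)
class ColumnMapping:
    column_name: str
    predicate_iri: str
    datatype: str  # date | boolean | integer | decimal | coded_text
    concept_code: Optional[str] = None
    value_codes: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.datatype not in ("date", "boolean", "integer", "decimal", "coded_text"):
            raise MappingError(
                f"column {self.column_name!r}: unknown datatype {self.datatype!r}"
            )
        if "://" not in self.predicate_iri:
            raise MappingError(
                f"column {self.column_name!r}: predicate IRI must be absolute,"
                f" got {self.predicate_iri!r}"
            )


@dataclass(frozen=True)
class OntologyMapping:
    base_namespace: str
    entries: tuple[ColumnMapping, ...]

    def __post_init__(self) -> None:
        names = [e.column_name for e in self.entries]
        if len(set(names)) != len(names):
            raise MappingError("duplicate column_name in mapping")

    def __getitem__(self, column: str) -> ColumnMapping:
        for e in self.entries:
            if e.column_name == column:
                return e
        raise MappingError(f"column {column!r} not present in mapping")

    def __contains__(self, column: str) -> bool:
        return any(e.column_name == column for e in self.entries)

    @property
    def prefixes(self) -> dict[str, str]:
        return {"fq": self.base_namespace}

    @classmethod
    def from_json(cls, source: Union[str, Path, dict]) -> "OntologyMapping":
        raw = (
            json.loads(Path(source).read_text(encoding="utf-8"))
            if isinstance(source, (str, Path))
            else source
        )
        try:
            base = raw["base_namespace"]
            columns = raw["columns"]
        except (KeyError, TypeError):
            raise MappingError("mapping needs 'base_namespace' and 'columns'") from None
        entries = []
        for name, info in columns.items():
            entries.append(
                ColumnMapping(
                    column_name=name,
                    predicate_iri=info["predicate_iri"],
                    datatype=info["datatype"],
                    concept_code=info.get("concept_code"),
                    value_codes=info.get("value_codes"),
                )
            )
        return cls(base_namespace=base, entries=tuple(entries))


def default_mapping() -> OntologyMapping:
    path = resources.files("fedqi").joinpath("data/default_mapping.json")
    return OntologyMapping.from_json(json.loads(path.read_text(encoding="utf-8")))


# --- vocabulary helpers ---------------------------------------------------

def _ns(mapping: OntologyMapping, local: str) -> IRI:
    return IRI(mapping.base_namespace + local)


def patient_class(mapping: OntologyMapping) -> IRI:
    return _ns(mapping, "Patient")


def patient_iri(mapping: OntologyMapping, center_id: str, patient_id: str) -> IRI:
    return _ns(mapping, f"patient/{center_id}/{patient_id}")


def concept_iri(mapping: OntologyMapping, column: str, value: str) -> IRI:
    return _ns(mapping, f"concept/{column}/{value}")


# --- triplify -------------------------------------------------------------

def _cell_value(record: PatientRecord, column: str):
    value = getattr(record, column)
    return value


def _object_term(
    mapping: OntologyMapping, cm: ColumnMapping, value, record_id: str
) -> Term:
    if cm.datatype == "date":
        return Literal(value.isoformat(), XSD_DATE)
    if cm.datatype == "boolean":
        return Literal("true" if value else "false", XSD_BOOLEAN)
    if cm.datatype == "integer":
        return Literal(str(int(value)), XSD_INTEGER)
    if cm.datatype == "decimal":
        return Literal(f"{float(value):.1f}", XSD_DECIMAL)
    # coded_text: with value_codes -> concept IRI; without -> plain string
    if cm.value_codes is not None:
        if str(value) not in cm.value_codes:
            raise MappingError(
                f"record {record_id!r}, column {cm.column_name!r}:"
                f" value {value!r} outside value_codes"
            )
        return concept_iri(mapping, cm.column_name, str(value))
    return Literal(str(value), XSD_STRING)


def triplify(table: FlatTable, mapping: OntologyMapping) -> Graph:
    """Convert a flat table into its FAIR graph.

    Emits, per record, one ``rdf:type`` triple plus one data triple per
    mapped non-missing cell; dataset-level terminology annotations (concept
    labels and codes, predicate codes) are added once per graph.
    """
    for column in CSV_COLUMNS:
        if column == "patient_id":
            continue
        if column not in mapping:
            raise MappingError(f"column {column!r} is not mapped")

    g = Graph()
    cls = patient_class(mapping)
    # dataset-level provenance triple
    g.add(_ns(mapping, f"dataset/{table.center_id}"), _ns(mapping, "centerId"),
          Literal(table.center_id, XSD_STRING))

    used_concepts: set[tuple[str, str]] = set()
    for record in table.records:
        subj = patient_iri(mapping, table.center_id, record.patient_id)
        g.add(subj, IRI(RDF_TYPE), cls)
        for column in CSV_COLUMNS:
            if column == "patient_id":
                continue
            value = _cell_value(record, column)
            if value is None:
                continue  # missing optional cell: no triple
            cm = mapping[column]
            obj = _object_term(mapping, cm, value, record.patient_id)
            g.add(subj, IRI(cm.predicate_iri), obj)
            if isinstance(obj, IRI) and cm.value_codes is not None:
                used_concepts.add((column, str(value)))

    # terminology annotations: concept labels + codes, predicate codes
    for column, value in sorted(used_concepts):
        cm = mapping[column]
        ci = concept_iri(mapping, column, value)
        g.add(ci, IRI(RDF_TYPE), _ns(mapping, "Concept"))
        g.add(ci, IRI(RDFS_LABEL), Literal(value, XSD_STRING))
        code = (cm.value_codes or {}).get(value)
        if code:
            g.add(ci, _ns(mapping, "terminologyCode"), Literal(code, XSD_STRING))
    for cm in mapping.entries:
        if cm.concept_code:
            g.add(IRI(cm.predicate_iri), _ns(mapping, "terminologyCode"),
                  Literal(cm.concept_code, XSD_STRING))
    return g


def patient_subject_triples(graph: Graph, mapping: OntologyMapping) -> list:
    """The per-record triples (type + data), excluding dataset-level annotations."""
    patients = set(graph.subjects(IRI(RDF_TYPE), patient_class(mapping)))
    return [t for t in graph if t[0] in patients]


# --- serialization --------------------------------------------------------

def serialize(
    graph: Graph,
    format: str = "turtle",
    path: Optional[Union[str, Path]] = None,
    mapping: Optional[OntologyMapping] = None,
) -> str:
    prefixes = (mapping or default_mapping()).prefixes
    text = graph.serialize(format=format, prefixes=prefixes)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_graph(path: Union[str, Path], format: Optional[str] = None) -> Graph:
    p = Path(path)
    if format is None:
        format = "ntriples" if p.suffix == ".nt" else "turtle"
    return Graph.parse(p.read_text(encoding="utf-8"), format=format)


# --- inverse view (round-trip testing) ------------------------------------

def _python_value(cm: ColumnMapping, term: Term, mapping: OntologyMapping, graph: Graph):
    if isinstance(term, IRI):
        label = graph.object(term, IRI(RDFS_LABEL))
        if label is None:
            raise MappingError(f"concept {term.value} has no label in graph")
        return label.to_python()
    v = term.to_python()
    if cm.datatype == "integer":
        return int(v)
    return v


def flat_view(graph: Graph, mapping: OntologyMapping) -> FlatTable:
    """Rebuild the flat table from a triplified graph (order not preserved)."""
    center_term = None
    for _, _, o in graph.triples(p=_ns(mapping, "centerId")):
        center_term = o
    patients = sorted(
        set(graph.subjects(IRI(RDF_TYPE), patient_class(mapping))), key=lambda s: s.value
    )
    records = []
    problems = []
    required = [
        c for c in CSV_COLUMNS if c not in ("patient_id", "date_neoadjuvant_start")
    ]
    for subj in patients:
        cells: dict[str, object] = {}
        for column in CSV_COLUMNS:
            if column == "patient_id":
                continue
            cm = mapping[column]
            term = graph.object(subj, IRI(cm.predicate_iri))
            if term is None:
                cells[column] = None
                continue
            cells[column] = _python_value(cm, term, mapping, graph)
        missing = [c for c in required if cells.get(c) is None]
        if missing:
            problems.append(f"{subj.value} missing {missing}")
            continue
        patient_id = subj.value.rsplit("/", 1)[-1]
        records.append(PatientRecord(patient_id=patient_id, **cells))  # type: ignore[arg-type]
    if problems:
        raise MappingError("subjects missing required predicates: " + "; ".join(problems))
    if center_term is not None:
        center_id = str(center_term.to_python())
    elif records:
        center_id = records[0].hospital_id
    else:
        center_id = ""
    return FlatTable(center_id=center_id, records=tuple(records))
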