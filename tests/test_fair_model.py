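"""Triplification: schema shape, counts, round trips, mapping errors."""

import random

import pytest

from fedqi import IRI, MappingError, OntologyMapping, flat_view, isomorphic, serialize, triplify
from fedqi._rdf import RDF_TYPE, XSD_STRING, Graph, Literal
from fedqi.fair_model import load_graph, patient_subject_triples
from fedqi.synthetic_ehr import CSV_COLUMNS, FlatTable

from conftest import make_record, random_table

N_MAPPED_COLUMNS = len(CSV_COLUMNS) - 1  # all but patient_id


def test_one_record_all_cells_present_gives_type_plus_data_triples(mapping):
    record = make_record(neoadjuvant=True)  # every optional cell populated
    g = triplify(FlatTable("c1", (record,)), mapping)
    per_record = patient_subject_triples(g, mapping)
    assert len(per_record) == 1 + N_MAPPED_COLUMNS  # 15: one type + 14 data


def test_missing_optional_cell_produces_no_triple(mapping):
    record = make_record(neoadjuvant=False)
    g = triplify(FlatTable("c1", (record,)), mapping)
    pred = IRI(mapping["date_neoadjuvant_start"].predicate_iri)
    assert list(g.triples(p=pred)) == []
    assert len(patient_subject_triples(g, mapping)) == 1 + N_MAPPED_COLUMNS - 1


def test_empty_table_has_no_patient_subjects(mapping):
    g = triplify(FlatTable("c1", ()), mapping)
    assert patient_subject_triples(g, mapping) == []


def test_triple_count_matches_direct_enumeration(mapping):
    # oracle: count non-missing mapped cells record by record
    table = random_table(random.Random(7), max_records=12)
    g = triplify(table, mapping)
    expected = sum(
        1 + sum(1 for c in CSV_COLUMNS if c != "patient_id" and getattr(r, c) is not None)
        for r in table.records
    )
    assert len(patient_subject_triples(g, mapping)) == expected


def test_every_data_predicate_is_in_the_mapping(mapping):
    table = random_table(random.Random(3), max_records=6)
    g = triplify(table, mapping)
    mapped = {e.predicate_iri for e in mapping.entries}
    for s, p, _ in patient_subject_triples(g, mapping):
        assert p.value == RDF_TYPE or p.value in mapped


def test_literals_carry_mapped_datatypes(mapping):
    from fedqi._rdf import XSD_BOOLEAN, XSD_DATE, XSD_DECIMAL, XSD_INTEGER

    g = triplify(FlatTable("c1", (make_record(),)), mapping)
    expect = {
        "dateOfSurgery": XSD_DATE,
        "referred": XSD_BOOLEAN,
        "age": XSD_INTEGER,
        "bodyMassIndex": XSD_DECIMAL,
    }
    for local, dt in expect.items():
        (_, _, o), = g.triples(p=IRI(mapping.base_namespace + local))
        assert isinstance(o, Literal) and o.datatype == dt


def test_coded_value_outside_value_codes_names_row_and_column(mapping):
    record = make_record(resection_type="unknown_procedure")
    with pytest.raises(MappingError, match=r"p1.*resection_type.*unknown_procedure"):
        triplify(FlatTable("c1", (record,)), mapping)


def test_unmapped_column_is_an_error(mapping):
    partial = OntologyMapping(
        base_namespace=mapping.base_namespace,
        entries=tuple(e for e in mapping.entries if e.column_name != "age"),
    )
    with pytest.raises(MappingError, match="age"):
        triplify(FlatTable("c1", (make_record(),)), mapping=partial)


def test_round_trip_identity_on_generated_table(mapping, center2_table):
    back = flat_view(triplify(center2_table, mapping), mapping)
    assert sorted(back.records, key=lambda r: r.patient_id) == sorted(
        center2_table.records, key=lambda r: r.patient_id
    )
    assert back.center_id == center2_table.center_id


def test_flat_view_ignores_unrelated_triples(mapping, small_table):
    g = triplify(small_table, mapping)
    g.add(IRI("https://other.org/x"), IRI("https://other.org/p"), Literal("noise", XSD_STRING))
    back = flat_view(g, mapping)
    assert len(back.records) == len(small_table.records)


def test_flat_view_empty_graph_gives_empty_table(mapping):
    assert flat_view(Graph(), mapping).records == ()


def test_flat_view_reports_subjects_missing_required_predicates(mapping):
    g = triplify(FlatTable("c1", (make_record(),)), mapping)
    subj = IRI(mapping.base_namespace + "patient/c1/broken")
    g.add(subj, IRI(RDF_TYPE), IRI(mapping.base_namespace + "Patient"))
    with pytest.raises(MappingError, match="broken"):
        flat_view(g, mapping)


@pytest.mark.parametrize("fmt,suffix", [("turtle", ".ttl"), ("ntriples", ".nt")])
def test_serialize_file_round_trip(tmp_path, mapping, small_table, fmt, suffix):
    g = triplify(small_table, mapping)
    path = tmp_path / f"g{suffix}"
    serialize(g, fmt, path, mapping=mapping)
    assert isomorphic(load_graph(path), g)


def test_both_formats_of_same_graph_are_isomorphic(tmp_path, mapping, small_table):
    g = triplify(small_table, mapping)
    ttl = Graph.parse(serialize(g, "turtle", mapping=mapping), "turtle")
    nt = Graph.parse(serialize(g, "ntriples", mapping=mapping), "ntriples")
    assert isomorphic(ttl, nt)


def test_mapping_file_errors():
    with pytest.raises(MappingError, match="base_namespace"):
        OntologyMapping.from_json({"columns": {}})
    with pytest.raises(MappingError, match="datatype"):
        OntologyMapping.from_json(
            {
                "base_namespace": "https://x/",
                "columns": {"age": {"predicate_iri": "https://x/age", "datatype": "complex"}},
            }
        )
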