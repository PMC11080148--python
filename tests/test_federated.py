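"""Train dispatch, payload auditing, and master-side aggregation."""

import math
import random

import pytest

from fedqi import (
    AccessPolicy,
    FederatedError,
    FlatTable,
    IndicatorSpec,
    Train,
    default_query,
    default_train,
    host_station,
    run_federated,
    run_train,
    triplify,
    validate_payload,
)
from fedqi._rdf import Graph

from conftest import random_table


def station_for(table, mapping, policy=None):
    return host_station(triplify(table, mapping), table.center_id, policy)


def test_run_train_center2_fixture_reproduces_published_rate(mapping, center2_table):
    res = run_train(station_for(center2_table, mapping), default_train("qi8"))
    assert (res.denominator, res.numerator) == (7, 4)
    assert f"{res.ratio:.3f}" == "0.571"


def test_run_train_on_empty_station_gives_undefined_ratio(mapping):
    station = host_station(Graph(), "empty")
    res = run_train(station, default_train("qi8"))
    assert (res.denominator, res.numerator, res.ratio) == (0, 0, None)


def test_payload_contains_exactly_the_aggregate_fields(mapping, center2_table):
    station = station_for(center2_table, mapping)
    station.accept_train(default_train("qi8"))
    payload = station.return_payload()
    assert set(payload) == {
        "center_id", "indicator_id", "denominator", "numerator", "ratio", "suppressed",
    }
    assert validate_payload(payload) == []


def test_malformed_query_produces_error_not_partial_data(mapping, center2_table):
    bad = Train("broken", "SELECT ?p WHERE { ?p", IndicatorSpec("qi8", "rectum"))
    with pytest.raises(FederatedError, match="broken"):
        run_train(station_for(center2_table, mapping), bad)


def test_suppression_replaces_small_cells_with_marker(mapping, center2_table):
    station = station_for(center2_table, mapping, AccessPolicy(min_cell_size=10))
    res = run_train(station, default_train("qi8"))  # counts 7 and 4 < 10
    assert res.suppressed
    assert res.numerator is None and res.denominator is None and res.ratio is None


def test_adversarial_train_smuggling_record_fields_is_rejected(mapping, center2_table):
    """A train whose payload carries patient-level data must not get past the audit."""

    def exfiltrate(rows, spec, center_id):
        return {
            "center_id": center_id,
            "indicator_id": spec.indicator_id,
            "denominator": len(rows),
            "numerator": 0,
            "ratio": 0.0,
            "suppressed": False,
            "patient_ids": [r["patient"] for r in rows],
        }

    bad = Train("adversary", default_query("qi8"), IndicatorSpec("qi8", "rectum"),
                local_algorithm=exfiltrate)
    with pytest.raises(FederatedError, match="patient_ids"):
        run_train(station_for(center2_table, mapping), bad)


@pytest.mark.parametrize(
    "mutation,expected",
    [
        ({"patient_ids": ["a", "b"]}, "patient_ids"),
        ({"numerator": 9}, "exceeds denominator"),
        ({"ratio": 0.9}, "ratio must equal"),
        ({"denominator": None}, "integer counts"),
        ({"numerator": 2.5}, "wrong type"),
    ],
)
def test_validate_payload_violations(mutation, expected):
    payload = {
        "center_id": "c",
        "indicator_id": "qi8",
        "denominator": 7,
        "numerator": 4,
        "ratio": 4 / 7,
        "suppressed": False,
    }
    payload.update(mutation)
    violations = validate_payload(payload)
    assert violations and any(expected in v for v in violations)


def test_validate_payload_passes_valid_and_zero_denominator_payloads():
    assert validate_payload(
        {"center_id": "c", "indicator_id": "qi8", "denominator": 0,
         "numerator": 0, "ratio": None, "suppressed": False}
    ) == []


def test_federated_mean_expected_events_and_rate_of_mean(mapping, small_table, center2_table):
    big = FlatTable("c1", small_table.records)
    stations = [station_for(big, mapping), station_for(center2_table, mapping)]
    result = run_federated(stations, default_train("qi8"))
    r1, r2 = (lr.ratio for lr in result.local_results)
    mean = (r1 + r2) / 2
    assert math.isclose(result.mean_ratio, mean)
    for lr in result.local_results:
        assert math.isclose(result.per_center_expected_events[lr.center_id], mean * lr.denominator)
        assert math.isclose(result.per_center_rate_of_mean[lr.center_id], lr.ratio / mean)


def test_mean_invariant_under_station_permutation(mapping, small_table, center2_table):
    a = station_for(FlatTable("c1", small_table.records), mapping)
    b = station_for(center2_table, mapping)
    train = default_train("qi8")
    fwd = run_federated([a, b], train)
    rev = run_federated([b, a], train)
    assert fwd.mean_ratio == rev.mean_ratio
    assert fwd.per_center_expected_events == rev.per_center_expected_events
    assert fwd.per_center_rate_of_mean == rev.per_center_rate_of_mean


def test_rate_of_mean_averages_to_one(mapping, small_table, center2_table):
    stations = [station_for(FlatTable("c1", small_table.records), mapping),
                station_for(center2_table, mapping)]
    result = run_federated(stations, default_train("qi8"))
    values = list(result.per_center_rate_of_mean.values())
    assert math.isclose(sum(values) / len(values), 1.0)


def test_single_station_mean_equals_its_ratio(mapping, center2_table):
    result = run_federated([station_for(center2_table, mapping)], default_train("qi8"))
    (lr,) = result.local_results
    assert result.mean_ratio == lr.ratio
    assert result.per_center_rate_of_mean[lr.center_id] == 1.0


@pytest.mark.parametrize("indicator_id", ["qi2b", "qi8"])
def test_federated_equals_pooled_computation(mapping, indicator_id):
    """Summed per-station counts equal the indicator computed on the pooled
    table (direct-scan oracle, no stations involved)."""
    from datetime import date

    from fedqi.indicators import first_therapy_date

    tables = [random_table(random.Random(seed), center_id=f"c{seed}", max_records=20)
              for seed in (10, 11, 12)]
    stations = [station_for(t, mapping) for t in tables]
    train = default_train(indicator_id)
    result = run_federated(stations, train)

    pooled = [r for t in tables for r in t.records]
    loc = train.indicator_spec.localization
    cohort = [r for r in pooled if r.tumor_localization == loc and not r.referred]
    if indicator_id == "qi8":
        expected_num = sum(r.postop_complication for r in cohort)
    else:
        expected_num = sum(
            (first_therapy_date(r.date_neoadjuvant_start, r.date_of_surgery)
             - r.date_of_diagnosis).days < 35
            for r in cohort
        )
    assert sum(lr.denominator for lr in result.local_results) == len(cohort)
    assert sum(lr.numerator for lr in result.local_results) == expected_num


def test_pooled_mean_mode(mapping, small_table, center2_table):
    stations = [station_for(FlatTable("c1", small_table.records), mapping),
                station_for(center2_table, mapping)]
    result = run_federated(stations, default_train("qi8"), mean_mode="pooled")
    num = sum(lr.numerator for lr in result.local_results)
    den = sum(lr.denominator for lr in result.local_results)
    assert result.mean_ratio == num / den


def test_all_stations_empty_is_an_error(mapping):
    stations = [host_station(Graph(), "e1"), host_station(Graph(), "e2")]
    with pytest.raises(FederatedError, match="no computable centers"):
        run_federated(stations, default_train("qi8"))


def test_no_stations_is_an_error():
    with pytest.raises(FederatedError, match="at least one station"):
        run_federated([], default_train("qi8"))


def test_train_json_round_trip(tmp_path):
    qpath = tmp_path / "q.rq"
    qpath.write_text(default_query("qi8"), encoding="utf-8")
    tpath = tmp_path / "train.json"
    tpath.write_text(
        '{"train_id": "t1", "query_file": "q.rq",'
        ' "indicator_spec": {"indicator_id": "qi8", "localization": "rectum"}}',
        encoding="utf-8",
    )
    train = Train.from_json(tpath)
    assert train.train_id == "t1"
    assert train.indicator_spec == IndicatorSpec("qi8", "rectum")
    assert "postoperativeComplication" in train.sparql_query
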