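"""Synthetic cohort generator: determinism, quotas, invariants, CSV I/O."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedqi import (
    ConfigError,
    GeneratorConfig,
    SchemaError,
    generate_center,
    read_flat_table,
    write_flat_table,
)
from fedqi.indicators import first_therapy_date
from fedqi.synthetic_ehr import WAITING_THRESHOLD_DAYS

from conftest import random_table


def cfg(**kw):
    base = dict(center_id="c1", n_patients=30, seed=5)
    base.update(kw)
    return GeneratorConfig(**base)


def test_generates_requested_number_of_records():
    assert len(generate_center(cfg(n_patients=40, seed=1))) == 40


def test_empty_cohort():
    assert len(generate_center(cfg(n_patients=0))) == 0


def test_same_seed_gives_byte_identical_csv(tmp_path):
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_flat_table(generate_center(cfg(seed=9)), a)
    write_flat_table(generate_center(cfg(seed=9)), b)
    assert a.read_bytes() == b.read_bytes()


def test_different_seed_differs(tmp_path):
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_flat_table(generate_center(cfg(seed=9)), a)
    write_flat_table(generate_center(cfg(seed=10)), b)
    assert a.read_bytes() != b.read_bytes()


def test_record_invariants_hold():
    table = generate_center(cfg(n_patients=300, seed=3, neoadjuvant_fraction=0.5))
    for r in table.records:
        assert r.date_of_diagnosis <= r.date_of_surgery
        if r.date_neoadjuvant_start is not None:
            assert r.date_of_diagnosis <= r.date_neoadjuvant_start <= r.date_of_surgery
        assert 1 <= r.asa_class <= 5
        assert r.age >= 0 and r.bmi > 0 and r.charlson_score >= 0
        assert r.hospital_id == "c1"
    assert len({r.patient_id for r in table.records}) == len(table)


@pytest.mark.parametrize(
    "quota",
    [
        {"rectum": (7, 4)},
        {"colon": (10, 7), "rectum": (7, 4)},
        {"colon": (25, 0), "rectum": (5, 5)},
    ],
)
def test_quota_marginals_exact(quota):
    table = generate_center(cfg(n_patients=40, seed=11, quota_counts=quota))
    nonreferred = [r for r in table.records if not r.referred]
    for loc, (denom, num) in quota.items():
        cohort = [r for r in nonreferred if r.tumor_localization == loc]
        assert len(cohort) == denom
        if loc == "rectum":
            assert sum(r.postop_complication for r in cohort) == num
        else:
            waits = [
                (first_therapy_date(r.date_neoadjuvant_start, r.date_of_surgery)
                 - r.date_of_diagnosis).days
                for r in cohort
            ]
            assert sum(w < WAITING_THRESHOLD_DAYS for w in waits) == num
    # filler records are referred so they stay outside the indicator cohorts
    assert sum(r.referred for r in table.records) == 40 - sum(d for d, _ in quota.values())


def test_quota_infeasible_raises():
    with pytest.raises(ConfigError, match="quota_counts"):
        generate_center(cfg(n_patients=5, quota_counts={"rectum": (7, 4)}))
    with pytest.raises(ConfigError, match="numerator"):
        generate_center(cfg(n_patients=20, quota_counts={"rectum": (4, 7)}))


def test_bernoulli_parameter_recovery_within_99pct_ci():
    p, n = 0.3, 5000
    table = generate_center(cfg(n_patients=n, seed=42, complication_prob=p, referred_fraction=0.0))
    phat = sum(r.postop_complication for r in table.records) / n
    half_width = 2.5758 * np.sqrt(p * (1 - p) / n)  # 99% normal-approx binomial CI
    assert abs(phat - p) <= half_width


@pytest.mark.parametrize(
    "field,value,match",
    [
        ("complication_prob", 1.5, "complication_prob"),
        ("rectum_fraction", -0.1, "rectum_fraction"),
        ("n_patients", -1, "n_patients"),
        ("waiting_time_days", {"name": "nosuch"}, "waiting_time_days"),
        ("age", {"name": "normal", "mean": 60}, "age"),
    ],
)
def test_config_errors_name_the_field(field, value, match):
    with pytest.raises(ConfigError, match=match):
        generate_center(cfg(**{field: value}))


def test_config_json_rejects_unknown_and_missing_fields():
    with pytest.raises(ConfigError, match="unknown config fields"):
        GeneratorConfig.from_json({"center_id": "c", "n_patients": 1, "seed": 1, "bogus": 2})
    with pytest.raises(ConfigError, match="missing required"):
        GeneratorConfig.from_json({"center_id": "c"})


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_csv_round_trip_is_identity(table_seed):
    import io

    table = random_table(random.Random(table_seed))
    buf = io.StringIO()
    table.to_dataframe().to_csv(buf, index=False)
    buf.seek(0)
    back = read_flat_table(buf)
    assert back.center_id == (table.center_id if len(table) else "")
    assert back.records == table.records


def test_round_trip_restores_absent_neoadjuvant_date(tmp_path):
    table = random_table(random.Random(1))
    assert any(r.date_neoadjuvant_start is None for r in table.records)
    path = tmp_path / "t.csv"
    write_flat_table(table, path)
    back = read_flat_table(path)
    assert back.records == table.records


def test_missing_column_names_it(tmp_path):
    path = tmp_path / "t.csv"
    df = generate_center(cfg(n_patients=3)).to_dataframe().drop(columns=["date_of_surgery"])
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="date_of_surgery"):
        read_flat_table(path)


def test_malformed_cell_names_row_and_column(tmp_path):
    path = tmp_path / "t.csv"
    df = generate_center(cfg(n_patients=3)).to_dataframe()
    df.loc[1, "date_of_surgery"] = "not-a-date"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match=r"row 1.*date_of_surgery"):
        read_flat_table(path)
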