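import random
from datetime import date, timedelta

import pytest

from fedqi import (
    FlatTable,
    GeneratorConfig,
    PatientRecord,
    default_mapping,
    generate_center,
)

RESECTIONS = (
    "low_anterior_resection",
    "abdominoperineal_resection",
    "sigmoid_resection",
    "right_hemicolectomy",
)


def make_record(
    patient_id="p1",
    hospital_id="c1",
    localization="rectum",
    referred=False,
    diagnosis=date(2021, 3, 1),
    wait_days=20,
    neoadjuvant=False,
    complication=False,
    **extra,
):
    """Hand-built record with an exactly controlled diagnosis-to-therapy wait."""
    if neoadjuvant:
        neo = diagnosis + timedelta(days=wait_days)
        surgery = neo + timedelta(days=30)
    else:
        neo = None
        surgery = diagnosis + timedelta(days=wait_days)
    fields = dict(
        patient_id=patient_id,
        hospital_id=hospital_id,
        tumor_localization=localization,
        referred=referred,
        date_of_diagnosis=diagnosis,
        date_neoadjuvant_start=neo,
        date_of_surgery=surgery,
        resection_type="low_anterior_resection" if localization == "rectum" else "sigmoid_resection",
        age=70,
        bmi=26.1,
        charlson_score=1,
        asa_class=2,
        preop_tumor_complication=False,
        postop_complication=complication,
    )
    fields.update(extra)
    return PatientRecord(**fields)


def random_table(rng: random.Random, center_id="cX", max_records=8) -> FlatTable:
    """Small randomized table exercising optional cells and both localizations."""
    n = rng.randint(0, max_records)
    records = []
    for i in range(n):
        records.append(
            make_record(
                patient_id=f"{center_id}-{i}",
                hospital_id=center_id,
                localization=rng.choice(["colon", "rectum"]),
                referred=rng.random() < 0.3,
                diagnosis=date(2021, 1, 1) + timedelta(days=rng.randint(0, 300)),
                wait_days=rng.randint(0, 80),
                neoadjuvant=rng.random() < 0.4,
                complication=rng.random() < 0.5,
                resection_type=rng.choice(RESECTIONS),
                age=rng.randint(20, 95),
                bmi=round(rng.uniform(16.0, 45.0), 1),
                charlson_score=rng.randint(0, 10),
                asa_class=rng.randint(1, 5),
                preop_tumor_complication=rng.random() < 0.25,
            )
        )
    return FlatTable(center_id=center_id, records=tuple(records))


@pytest.fixture(scope="session")
def mapping():
    return default_mapping()


@pytest.fixture(scope="session")
def small_table():
    """Deterministic 17-record table: 7 rectum (4 complications), 10 colon."""
    records = []
    for i in range(7):
        records.append(
            make_record(
                patient_id=f"r{i}",
                localization="rectum",
                complication=i < 4,
                wait_days=10 + i,
                neoadjuvant=i % 2 == 0,
            )
        )
    for i in range(10):
        records.append(
            make_record(
                patient_id=f"c{i}",
                localization="colon",
                wait_days=10 if i < 7 else 50,  # 7 short waits
                complication=i % 3 == 0,
            )
        )
    return FlatTable(center_id="c1", records=tuple(records))


@pytest.fixture(scope="session")
def center2_table():
    """Quota-generated small-center fixture: colon 10/7 short-wait, rectum 7/4 complications."""
    config = GeneratorConfig(
        center_id="center2",
        n_patients=40,
        seed=202,
        quota_counts={"colon": (10, 7), "rectum": (7, 4)},
    )
    return generate_center(config)
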