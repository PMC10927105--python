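import datetime as dt

import pytest

from sitesel.cohort_rwd import aggregate_hco, apply_cohort, derive_referrals
from sitesel.data_model import ClaimRecord, to_frame
from sitesel.evaluation import split_sites
from sitesel.recruitment_features import assemble, clip_and_impute
from sitesel.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest linked bundle reused across tests (fixed seed)."""
    return generate_dataset(GeneratorConfig(n_sites=40, n_studies=10, seed=7))


@pytest.fixture(scope="session")
def small_claims_frame(small_dataset):
    return to_frame(small_dataset.claims, ClaimRecord)


@pytest.fixture(scope="session")
def prepared(small_dataset, small_claims_frame):
    """Cohort-filtered claims, aggregates, clipped feature table and split."""
    ds = small_dataset
    filtered = apply_cohort(small_claims_frame, ds.cohort)
    referrals = derive_referrals(filtered)
    aggregates = aggregate_hco(
        filtered,
        referrals,
        to_frame(ds.publications),
        to_frame(ds.trials),
        ds.cohort.specialist_types,
    )
    table = assemble(to_frame(ds.enrollment), aggregates)
    split = split_sites(table.frame["site_id"], train_frac=0.8, seed=7)
    train_mask = split.mask(table.frame, "train").to_numpy()
    table = clip_and_impute(table, train_mask)
    return {
        "dataset": ds,
        "filtered": filtered,
        "referrals": referrals,
        "aggregates": aggregates,
        "table": table,
        "split": split,
        "train_mask": train_mask,
    }


def claim(
    patient="P1",
    hco="H1",
    physician="D1",
    specialty="SPECIALIST",
    date="2020-06-01",
    visit="V1",
    diag=("D10",),
    drugs=(),
    procs=(),
    age=50,
) -> ClaimRecord:
    """Terse hand-fixture constructor for claim lines."""
    return ClaimRecord(
        patient_id=patient,
        hco_id=hco,
        physician_id=physician,
        specialty=specialty,
        service_date=dt.date.fromisoformat(date),
        visit_id=visit,
        diagnosis_codes=frozenset(diag),
        drug_codes=frozenset(drugs),
        procedure_codes=frozenset(procs),
        patient_age=age,
    )
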