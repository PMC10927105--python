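"""Cohort filtering of claims and HCO-level real-world-data covariates.

Applies a :class:`~sitesel.data_model.CohortDefinition` to encounter lines
and aggregates, per healthcare organization (HCO), the covariates that
characterize its clinical practice for the indication: unique relevant
claims, patients, treated patients, visits, physicians, treating
physicians, specialists, referral-flow differences, publication and
trial-participation counts.

Referral events are derived from longitudinal patient journeys: two
consecutive qualifying encounters of the same patient at distinct HCOs
within ``gap_days`` constitute a referral from the earlier to the later
HCO.  The 90-day default is a conventional care-transition window and is
configurable.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ClaimRecord, CohortDefinition, to_frame
from .errors import ConfigError

__all__ = [
    "apply_cohort",
    "derive_referrals",
    "aggregate_hco",
    "HCO_AGGREGATE_COLUMNS",
]

HCO_AGGREGATE_COLUMNS = [
    "n_claims",
    "n_patients",
    "n_treated_patients",
    "n_visits",
    "visits_per_patient",
    "n_physicians",
    "n_treating_physicians",
    "n_specialists",
    "patient_flow_difference",
    "site_flow_difference",
    "n_publications",
    "n_ongoing_trials",
    "n_sponsor_trials",
    "trial_experience",
]


def _claims_frame(claims) -> pd.DataFrame:
    if isinstance(claims, pd.DataFrame):
        return claims
    return to_frame(list(claims), ClaimRecord)


def apply_cohort(claims, cohort: CohortDefinition) -> pd.DataFrame:
    """Filter claims to the cohort and flag treated patients.

    A claim is retained when its service date lies in the half-open
    observation window, the patient age is within the cohort age range, and
    its diagnosis codes intersect the cohort's.  A patient is *treated* when
    any of their retained claims carries a cohort drug or procedure code;
    the returned frame adds a boolean ``patient_treated`` column.
    Idempotent: re-applying the cohort to its own output is a no-op.
    """
    cohort.validate()
    frame = _claims_frame(claims)
    if frame.empty:
        out = frame.copy()
        out["claim_treatment"] = pd.Series(dtype=bool)
        out["patient_treated"] = pd.Series(dtype=bool)
        return out
    start = pd.Timestamp(cohort.observation_start)
    end = pd.Timestamp(cohort.observation_end)
    dates = pd.to_datetime(frame["service_date"])
    in_window = (dates >= start) & (dates < end)
    in_age = frame["patient_age"].between(cohort.min_age, cohort.max_age)
    diag = frame["diagnosis_codes"].map(
        lambda codes: bool(frozenset(codes) & cohort.diagnosis_codes)
    )
    out = frame.loc[in_window & in_age & diag].copy()
    if out.empty:
        out["claim_treatment"] = pd.Series(dtype=bool)
        out["patient_treated"] = pd.Series(dtype=bool)
        return out
    treat_codes = cohort.drug_codes | cohort.procedure_codes
    has_treatment = out.apply(
        lambda row: bool(
            (frozenset(row["drug_codes"]) | frozenset(row["procedure_codes"]))
            & treat_codes
        ),
        axis=1,
    )
    treated_patients = set(out.loc[has_treatment, "patient_id"])
    out["claim_treatment"] = has_treatment
    out["patient_treated"] = out["patient_id"].isin(treated_patients)
    return out


def derive_referrals(filtered_claims: pd.DataFrame, gap_days: int = 90) -> pd.DataFrame:
    """Referral events from patient journeys across HCOs.

    Claims are collapsed to (patient, date, HCO) encounters and sorted within
    patient by date (ties by HCO id for determinism).  Each ordered pair of
    consecutive encounters at distinct HCOs within ``gap_days`` yields one
    event ``from_hco -> to_hco`` dated at the receiving encounter.
    """
    if gap_days <= 0:
        raise ConfigError(f"gap_days must be positive, got {gap_days}")
    frame = _claims_frame(filtered_claims)
    if frame.empty:
        return pd.DataFrame(columns=["patient_id", "from_hco", "to_hco", "date"])
    enc = (
        frame[["patient_id", "service_date", "hco_id"]]
        .drop_duplicates()
        .sort_values(["patient_id", "service_date", "hco_id"], kind="mergesort")
    )
    events = []
    for patient_id, grp in enc.groupby("patient_id", sort=False):
        hcos = grp["hco_id"].to_numpy()
        dates = grp["service_date"].to_numpy()
        for k in range(1, len(hcos)):
            if hcos[k] != hcos[k - 1]:
                gap = (dates[k] - dates[k - 1]) / np.timedelta64(1, "D")
                if gap <= gap_days:
                    events.append(
                        (patient_id, hcos[k - 1], hcos[k], dates[k])
                    )
    return pd.DataFrame(events, columns=["patient_id", "from_hco", "to_hco", "date"])


def aggregate_hco(
    filtered_claims: pd.DataFrame,
    referrals: pd.DataFrame | None = None,
    publications: pd.DataFrame | Sequence | None = None,
    trials: pd.DataFrame | Sequence | None = None,
    specialist_types: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-HCO covariate aggregates, indexed by ``hco_id``.

    Counts follow the covariate-table definitions: unique claims, patients,
    visits and physicians on relevant claims; treated patients / treating
    physicians via cohort drug-or-procedure codes; specialists by specialty
    label; publication count as the max across the site's physicians;
    patient flow difference = incoming - outgoing referral events; site
    flow difference = distinct referring sites - distinct referred-to sites;
    ``trial_experience`` = the site has at least one trial record.
    """
    frame = _claims_frame(filtered_claims)
    specialist_types = frozenset(specialist_types)
    pubs = _as_plain_frame(publications, ["physician_id", "hco_id", "n_publications"])
    trl = _as_plain_frame(trials, ["hco_id", "trial_id", "sponsor_flag",
                                   "ongoing_flag"])

    hcos = sorted(set(frame["hco_id"])) if not frame.empty else []
    agg = pd.DataFrame(index=pd.Index(hcos, name="hco_id"),
                       columns=HCO_AGGREGATE_COLUMNS, dtype=float)
    if frame.empty:
        return agg

    grouped = frame.groupby("hco_id")
    agg["n_claims"] = grouped.size()
    agg["n_patients"] = grouped["patient_id"].nunique()
    agg["n_visits"] = grouped["visit_id"].nunique()
    agg["n_physicians"] = grouped["physician_id"].nunique()

    if "patient_treated" in frame.columns:
        treated = frame[frame["patient_treated"]]
    else:
        treated = frame.iloc[0:0]
    agg["n_treated_patients"] = treated.groupby("hco_id")["patient_id"].nunique()

    if "claim_treatment" in frame.columns:
        treat_claim = frame["claim_treatment"].astype(bool)
    else:
        treat_claim = frame.apply(
            lambda row: bool(frozenset(row["drug_codes"])
                             | frozenset(row["procedure_codes"])),
            axis=1,
        )
    agg["n_treating_physicians"] = (
        frame[treat_claim].groupby("hco_id")["physician_id"].nunique()
    )
    specialists = frame[frame["specialty"].isin(specialist_types)]
    agg["n_specialists"] = specialists.groupby("hco_id")["physician_id"].nunique()

    if referrals is not None and not referrals.empty:
        incoming = referrals.groupby("to_hco").size()
        outgoing = referrals.groupby("from_hco").size()
        senders = referrals.groupby("to_hco")["from_hco"].nunique()
        receivers = referrals.groupby("from_hco")["to_hco"].nunique()
        agg["patient_flow_difference"] = incoming.reindex(agg.index).fillna(0) - \
            outgoing.reindex(agg.index).fillna(0)
        agg["site_flow_difference"] = senders.reindex(agg.index).fillna(0) - \
            receivers.reindex(agg.index).fillna(0)

    if pubs is not None and not pubs.empty:
        agg["n_publications"] = pubs.groupby("hco_id")["n_publications"].max()
    if trl is not None and not trl.empty:
        by_site = trl.groupby("hco_id")
        agg["n_ongoing_trials"] = by_site["ongoing_flag"].sum()
        agg["n_sponsor_trials"] = by_site["sponsor_flag"].sum()
        agg["trial_experience"] = (by_site.size() > 0).astype(float)

    zero_default = [c for c in HCO_AGGREGATE_COLUMNS if c != "visits_per_patient"]
    agg[zero_default] = agg[zero_default].fillna(0.0)
    agg["visits_per_patient"] = np.where(
        agg["n_patients"] > 0, agg["n_visits"] / agg["n_patients"].replace(0, 1), 0.0
    )
    return agg.astype(float)


def _as_plain_frame(obj, columns: list[str]) -> pd.DataFrame | None:
    if obj is None:
        return None
    if isinstance(obj, pd.DataFrame):
        return obj
    seq = list(obj)
    if not seq:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([{c: getattr(r, c) for c in columns} for r in seq])
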