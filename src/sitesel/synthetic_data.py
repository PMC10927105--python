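"""Synthetic claims, enrollment-history, publication and trial tables.

Real site-selection exercises draw on proprietary sources: a claims
database with longitudinal patient journeys, a trial-recruitment database
with per-(study, site) enrollment, and publication / trial-participation
aggregates.  This module generates linked tables with the statistical
structure the downstream analysis assumes, together with the generating
parameters (:class:`GroundTruth`) so that estimators can be checked by
parameter recovery:

* each site has a latent size factor ``s_i ~ Gamma(shape, scale)``;
  site-level covariates are gamma draws whose means scale with ``s_i``,
  so covariates are right-skewed and mutually correlated, as they are in
  claims data;
* per (study, site) row the enrolled count is Poisson with mean
  ``E * exp(eta)``, where ``E`` is the enrollment-months exposure and
  ``eta = intercept + sum_j beta_j z_j + nonlinear_strength * z_a * z_b``
  on z-scored covariates;
* a configurable fraction of patients visit a second HCO later in time,
  inducing the cross-HCO journeys from which referral flows are derived.

A fixed seed yields bit-identical tables.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    DAYS_PER_MONTH,
    ClaimRecord,
    CohortDefinition,
    PublicationRecord,
    StudySiteEnrollment,
    TrialParticipationRecord,
    save_cohort,
    write_table,
)
from .errors import ConfigError

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "default_cohort",
    "generate_sites",
    "generate_site_covariates",
    "generate_claims",
    "generate_enrollment",
    "generate_dataset",
]

# Typical magnitudes for claim-derivable covariates (per average-size site).
DEFAULT_COVARIATE_MEANS: dict[str, float] = {
    "n_patients": 80.0,
    "n_specialists": 5.0,
    "n_publications": 12.0,
    "n_ongoing_trials": 4.0,
}
_FALLBACK_COVARIATE_MEAN = 10.0

DEFAULT_BETA: dict[str, float] = {
    "n_patients": 0.4,
    "n_specialists": 0.2,
    "n_publications": 0.15,
    "n_ongoing_trials": 0.1,
}


def default_cohort() -> CohortDefinition:
    """Cohort definition used by the generator unless one is supplied.

    Small abstract vocabularies stand in for ICD/NDC/CPT code lists; the
    observation window mirrors the availability of US claims data from 2016.
    """
    return CohortDefinition(
        observation_start=dt.date(2016, 1, 1),
        observation_end=dt.date(2024, 1, 1),
        min_age=18,
        max_age=80,
        diagnosis_codes=frozenset({"D10", "D11", "D12"}),
        drug_codes=frozenset({"R01", "R02"}),
        procedure_codes=frozenset({"P01"}),
        specialist_types=frozenset({"SPECIALIST"}),
    )


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study.

    ``beta`` maps covariate names to log-rate coefficients applied to the
    z-scored covariate; ``nonlinear_strength`` is the coefficient of the
    multiplicative interaction of ``nonlinear_pair`` added to the log rate.
    ``noise_covariates`` are generated independently of site size and carry
    no effect on enrollment.
    """

    n_sites: int = 200
    n_studies: int = 20
    years_span: int = 10
    seed: int = 0
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    intercept: float = -1.3
    nonlinear_strength: float = 0.3
    nonlinear_pair: tuple[str, str] = ("n_patients", "n_specialists")
    site_size_shape: float = 2.0
    site_size_scale: float = 5.0
    mean_enrollment_months: float = 12.0
    referral_rate: float = 0.1
    study_site_frac_min: float = 0.3
    months_quality_corr: float = 0.0
    treated_frac: float = 0.6
    nonqualifying_frac: float = 0.3
    covariate_shape: float = 4.0
    noise_covariates: tuple[str, ...] = ("noise_gamma",)
    enrollment_start: dt.date = dt.date(2014, 1, 1)

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ConfigError("n_sites must be >= 2")
        if self.n_studies < 2:
            raise ConfigError("n_studies must be >= 2")
        for name in ("referral_rate", "treated_frac"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name in ("site_size_shape", "site_size_scale", "covariate_shape"):
            v = getattr(self, name)
            if v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if self.mean_enrollment_months < 1.0:
            raise ConfigError("mean_enrollment_months must be >= 1 month")
        if self.nonlinear_strength < 0:
            raise ConfigError("nonlinear_strength must be >= 0")
        if not 0.0 < self.study_site_frac_min <= 1.0:
            raise ConfigError("study_site_frac_min must be in (0, 1]")

    @property
    def covariate_names(self) -> list[str]:
        names = list(self.beta)
        for name in self.nonlinear_pair:
            if self.nonlinear_strength > 0 and name not in names:
                names.append(name)
        for name in self.noise_covariates:
            if name not in names:
                names.append(name)
        return names


@dataclass
class GroundTruth:
    """Generating parameters and per-row true log rates.

    ``exp(eta) * enrollment_months`` is each row's Poisson mean; ``site_z``
    holds the z-scored covariates the log rate was computed from.
    """

    beta: dict[str, float]
    intercept: float
    nonlinear_strength: float
    nonlinear_pair: tuple[str, str]
    site_sizes: pd.Series  # latent size factor, indexed by site_id
    site_covariates: pd.DataFrame  # raw gamma covariates, indexed by site_id
    site_z: pd.DataFrame  # z-scored covariates, indexed by site_id
    rows: pd.DataFrame  # study_id, site_id, eta

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "beta": self.beta,
            "intercept": self.intercept,
            "nonlinear_strength": self.nonlinear_strength,
            "nonlinear_pair": list(self.nonlinear_pair),
            "site_sizes": self.site_sizes.to_dict(),
            "site_covariates": self.site_covariates.to_dict(orient="index"),
            "site_z": self.site_z.to_dict(orient="index"),
            "rows": self.rows.to_dict(orient="records"),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            beta=raw["beta"],
            intercept=raw["intercept"],
            nonlinear_strength=raw["nonlinear_strength"],
            nonlinear_pair=tuple(raw["nonlinear_pair"]),
            site_sizes=pd.Series(raw["site_sizes"]),
            site_covariates=pd.DataFrame.from_dict(raw["site_covariates"],
                                                   orient="index"),
            site_z=pd.DataFrame.from_dict(raw["site_z"], orient="index"),
            rows=pd.DataFrame(raw["rows"]),
        )


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent named streams so each stage is deterministic regardless of
    # which other stages run
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def generate_sites(config: GeneratorConfig) -> pd.DataFrame:
    """Site registry with latent size factors ``s_i ~ Gamma(shape, scale)``."""
    config.validate()
    rng = _rng(config, 0)
    sizes = rng.gamma(config.site_size_shape, config.site_size_scale,
                      size=config.n_sites)
    width = max(4, len(str(config.n_sites)))
    site_ids = [f"H{i:0{width}d}" for i in range(1, config.n_sites + 1)]
    return pd.DataFrame({"site_id": site_ids, "size_factor": sizes})


def generate_site_covariates(
    config: GeneratorConfig, sites: pd.DataFrame
) -> pd.DataFrame:
    """Per-site gamma covariates; signal covariates scale with site size,
    noise covariates are independent of it."""
    rng = _rng(config, 1)
    rel_size = sites["size_factor"].to_numpy()
    rel_size = rel_size / rel_size.mean()
    shape = config.covariate_shape
    out = {}
    for name in config.covariate_names:
        base = DEFAULT_COVARIATE_MEANS.get(name, _FALLBACK_COVARIATE_MEAN)
        if name in config.noise_covariates:
            mean = np.full(len(sites), base)
        else:
            mean = base * rel_size
        out[name] = rng.gamma(shape, mean / shape)
    return pd.DataFrame(out, index=pd.Index(sites["site_id"], name="site_id"))


def _zscore(frame: pd.DataFrame) -> pd.DataFrame:
    mu = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (frame - mu) / sd


def generate_claims(
    config: GeneratorConfig,
    sites: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cohort: CohortDefinition | None = None,
) -> list[ClaimRecord]:
    """Encounter lines per site: cohort-qualifying patients (counts tracking
    the ``n_patients`` covariate), specialist and generalist physicians,
    treatment codes for a fraction of patients, some non-qualifying
    patients, and second-HCO encounters for a ``referral_rate`` fraction."""
    config.validate()
    cohort = cohort or default_cohort()
    if covariates is None:
        covariates = generate_site_covariates(config, sites)
    rng = _rng(config, 2)
    window_days = (cohort.observation_end - cohort.observation_start).days
    diag_codes = sorted(cohort.diagnosis_codes)
    drug_codes = sorted(cohort.drug_codes)
    proc_codes = sorted(cohort.procedure_codes)
    spec_types = sorted(cohort.specialist_types) or ["SPECIALIST"]
    site_ids = list(sites["site_id"])
    rel_size = sites["size_factor"].to_numpy()
    rel_size = rel_size / rel_size.mean()

    records: list[ClaimRecord] = []
    referral_candidates: list[tuple[str, int, dt.date]] = []  # patient, age, last date
    patient_home: dict[str, str] = {}
    visit_counter = 0

    def _date(day_offset: int) -> dt.date:
        return cohort.observation_start + dt.timedelta(days=int(day_offset))

    for idx, site_id in enumerate(site_ids):
        if "n_patients" in covariates.columns:
            n_q = int(round(covariates.loc[site_id, "n_patients"]))
        else:
            n_q = int(round(20 * rel_size[idx]))
        n_q = max(1, n_q)
        if "n_specialists" in covariates.columns:
            n_spec = int(round(covariates.loc[site_id, "n_specialists"]))
        else:
            n_spec = max(1, int(round(2 * rel_size[idx])))
        n_gen = max(1, n_q // 25)
        physicians = [
            (f"{site_id}-S{k:03d}", spec_types[k % len(spec_types)])
            for k in range(n_spec)
        ] + [(f"{site_id}-G{k:03d}", "INTERNAL_MED") for k in range(n_gen)]

        def _emit(patient_id, hco_id, age, date, diag, drugs, procs):
            nonlocal visit_counter
            visit_counter += 1
            visit_id = f"V{visit_counter:08d}"
            phys, spec = physicians[rng.integers(len(physicians))]
            # some visits produce a second claim line (same visit id), so
            # claim counts exceed visit counts as in real adjudication data
            n_lines = 2 if rng.random() < 0.25 else 1
            for line in range(n_lines):
                if line > 0:
                    diag = [diag_codes[int(rng.integers(len(diag_codes)))]]
                    drugs, procs = [], []
                records.append(
                    ClaimRecord(
                        patient_id=patient_id,
                        hco_id=hco_id,
                        physician_id=phys,
                        specialty=spec,
                        service_date=date,
                        visit_id=visit_id,
                        diagnosis_codes=frozenset(diag),
                        drug_codes=frozenset(drugs),
                        procedure_codes=frozenset(procs),
                        patient_age=int(age),
                    )
                )

        for p in range(n_q):
            patient_id = f"P-{site_id}-{p:05d}"
            patient_home[patient_id] = site_id
            age = int(rng.integers(cohort.min_age, cohort.max_age + 1))
            n_visits = 1 + int(rng.poisson(1.2))
            days = np.sort(rng.integers(0, window_days, size=n_visits))
            treated = rng.random() < config.treated_frac
            for v, day in enumerate(days):
                diag = [diag_codes[int(rng.integers(len(diag_codes)))]]
                drugs, procs = [], []
                if treated and v == len(days) - 1:
                    if drug_codes and (not proc_codes or rng.random() < 0.7):
                        drugs = [drug_codes[int(rng.integers(len(drug_codes)))]]
                    elif proc_codes:
                        procs = [proc_codes[int(rng.integers(len(proc_codes)))]]
                _emit(patient_id, site_id, age, _date(day), diag, drugs, procs)
            if rng.random() < config.referral_rate and config.n_sites > 1:
                referral_candidates.append((patient_id, age, _date(days[-1])))

        # non-qualifying patients: wrong age or an off-cohort diagnosis
        n_nq = int(round(config.nonqualifying_frac * n_q))
        for p in range(n_nq):
            patient_id = f"Q-{site_id}-{p:05d}"
            if rng.random() < 0.5:
                age = int(rng.integers(0, max(1, cohort.min_age)))
                diag = [diag_codes[int(rng.integers(len(diag_codes)))]]
            else:
                age = int(rng.integers(cohort.min_age, cohort.max_age + 1))
                diag = ["OTHER"]
            day = int(rng.integers(0, window_days))
            _emit(patient_id, site_id, age, _date(day), diag, [], [])

    # second-HCO encounters (the later encounter is at the receiving site)
    for patient_id, age, last_date in referral_candidates:
        home = patient_home[patient_id]
        others = [s for s in site_ids if s != home]
        dest = others[int(rng.integers(len(others)))]
        gap = int(rng.integers(7, 61))
        date = min(last_date + dt.timedelta(days=gap),
                   cohort.observation_end - dt.timedelta(days=1))
        diag = [diag_codes[int(rng.integers(len(diag_codes)))]]
        visit_counter += 1
        records.append(
            ClaimRecord(
                patient_id=patient_id,
                hco_id=dest,
                physician_id=f"{dest}-G000",
                specialty="INTERNAL_MED",
                service_date=date,
                visit_id=f"V{visit_counter:08d}",
                diagnosis_codes=frozenset(diag),
                drug_codes=frozenset(),
                procedure_codes=frozenset(),
                patient_age=int(age),
            )
        )
    return records


def generate_enrollment(
    config: GeneratorConfig,
    sites: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> tuple[list[StudySiteEnrollment], GroundTruth]:
    """Per-(study, site) enrollment rows with Poisson counts.

    Each study samples a random subset of sites (at least
    ``study_site_frac_min`` of them); site open dates are uniform over the
    configured span; exposure is a shifted exponential with the configured
    mean and a floor of one month; the count is Poisson with mean
    ``E * exp(eta)`` on z-scored covariates.
    """
    config.validate()
    if covariates is None:
        covariates = generate_site_covariates(config, sites)
    rng = _rng(config, 3)
    # effects act on standardized *log* covariates: gamma-distributed
    # covariates are heavily right-skewed, and an elasticity-style effect
    # keeps the log-rate tails (and hence the count distribution) in the
    # realistic few-to-tens-of-patients range
    z = _zscore(np.log(covariates.clip(lower=1e-9)))
    beta = pd.Series(dict(config.beta), dtype=float)
    missing = [c for c in beta.index if c not in z.columns]
    if missing:
        raise ConfigError(f"beta names covariates absent from the table: {missing}")
    eta_site = pd.Series(config.intercept, index=z.index, dtype=float)
    for name, coef in beta.items():
        eta_site = eta_site + coef * z[name]
    if config.nonlinear_strength > 0:
        a, b = config.nonlinear_pair
        eta_site = eta_site + config.nonlinear_strength * z[a] * z[b]
    if np.exp(eta_site.max()) > 1e8:
        raise ConfigError(
            "exp(log-rate) overflows a sane Poisson mean; use smaller beta "
            "or intercept"
        )

    span_days = int(config.years_span * 365.25)
    site_ids = np.asarray(sites["site_id"], dtype=object)
    rows: list[StudySiteEnrollment] = []
    gt_rows = []
    for j in range(1, config.n_studies + 1):
        study_id = f"S{j:03d}"
        frac = rng.uniform(config.study_site_frac_min, 1.0)
        m = max(2, int(round(frac * len(site_ids))))
        chosen = rng.choice(site_ids, size=min(m, len(site_ids)), replace=False)
        for site_id in sorted(chosen):
            open_date = config.enrollment_start + dt.timedelta(
                days=int(rng.integers(0, span_days))
            )
            e_months = 1.0 + rng.exponential(config.mean_enrollment_months - 1.0)
            if config.months_quality_corr != 0.0:
                e_months = 1.0 + (e_months - 1.0) * float(
                    np.exp(config.months_quality_corr * eta_site[site_id])
                )
            eta = float(eta_site[site_id])
            y = int(rng.poisson(e_months * np.exp(eta)))
            if y > 0:
                last = open_date + dt.timedelta(
                    days=int(round(e_months * DAYS_PER_MONTH))
                )
                first_frac = rng.uniform(0.05, 0.5)
                first = open_date + dt.timedelta(
                    days=int(round(first_frac * e_months * DAYS_PER_MONTH))
                )
            else:
                first = last = None
            rows.append(
                StudySiteEnrollment(
                    study_id=study_id,
                    site_id=str(site_id),
                    site_open_date=open_date,
                    first_subject_date=first,
                    last_subject_date=last,
                    enrollment_months=float(e_months),
                    patients_enrolled=y,
                )
            )
            gt_rows.append({"study_id": study_id, "site_id": str(site_id),
                            "eta": eta})

    ground_truth = GroundTruth(
        beta=dict(config.beta),
        intercept=config.intercept,
        nonlinear_strength=config.nonlinear_strength,
        nonlinear_pair=tuple(config.nonlinear_pair),
        site_sizes=sites.set_index("site_id")["size_factor"],
        site_covariates=covariates,
        site_z=z,
        rows=pd.DataFrame(gt_rows),
    )
    return rows, ground_truth


def _generate_publications(
    config: GeneratorConfig,
    covariates: pd.DataFrame,
    claims: Sequence[ClaimRecord],
) -> list[PublicationRecord]:
    rng = _rng(config, 4)
    by_site: dict[str, set[str]] = {}
    for rec in claims:
        by_site.setdefault(rec.hco_id, set()).add(rec.physician_id)
    records = []
    for site_id in sorted(by_site):
        physicians = sorted(by_site[site_id])
        if site_id in covariates.index and "n_publications" in covariates.columns:
            top = int(round(covariates.loc[site_id, "n_publications"]))
        else:
            top = int(rng.poisson(3))
        for k, phys in enumerate(physicians):
            n_pub = top if k == 0 else int(rng.integers(0, top + 1))
            if n_pub > 0 or k == 0:
                records.append(
                    PublicationRecord(physician_id=phys, hco_id=site_id,
                                      n_publications=n_pub)
                )
    return records


def _generate_trials(
    config: GeneratorConfig, covariates: pd.DataFrame
) -> list[TrialParticipationRecord]:
    rng = _rng(config, 5)
    records = []
    counter = 0
    for site_id in covariates.index:
        if "n_ongoing_trials" in covariates.columns:
            n_on = int(round(covariates.loc[site_id, "n_ongoing_trials"]))
        else:
            n_on = int(rng.poisson(2))
        n_closed = int(rng.poisson(1.0))
        for i in range(n_on + n_closed):
            counter += 1
            records.append(
                TrialParticipationRecord(
                    hco_id=str(site_id),
                    trial_id=f"NCT{counter:07d}",
                    sponsor_flag=bool(rng.random() < 0.3),
                    ongoing_flag=i < n_on,
                )
            )
    return records


def covariate_level_frame(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Enrollment rows joined with the raw site covariates, skipping the
    claims pipeline — the working table for simulation studies (parameter
    recovery, model comparisons) where the measured-covariate noise of the
    claims stage is not under test."""
    from .data_model import to_frame

    sites = generate_sites(config)
    covariates = generate_site_covariates(config, sites)
    rows, ground_truth = generate_enrollment(config, sites, covariates)
    frame = to_frame(rows, StudySiteEnrollment).merge(
        covariates.reset_index(), on="site_id"
    )
    frame = frame.drop(
        columns=["site_open_date", "first_subject_date", "last_subject_date"]
    )
    return frame, ground_truth


@dataclass
class SyntheticDataset:
    """All generated tables plus the ground truth, writable via the
    canonical table writers."""

    config: GeneratorConfig
    cohort: CohortDefinition
    sites: pd.DataFrame
    covariates: pd.DataFrame
    claims: list[ClaimRecord]
    enrollment: list[StudySiteEnrollment]
    publications: list[PublicationRecord]
    trials: list[TrialParticipationRecord]
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "claims": write_table(self.claims, out / "claims.csv", ClaimRecord),
            "enrollment": write_table(
                self.enrollment, out / "enrollment.csv", StudySiteEnrollment
            ),
            "publications": write_table(
                self.publications, out / "publications.csv", PublicationRecord
            ),
            "trials": write_table(
                self.trials, out / "trials.csv", TrialParticipationRecord
            ),
            "cohort": save_cohort(self.cohort, out / "cohort.yaml"),
            "ground_truth": self.ground_truth.to_json(out / "ground_truth.json"),
        }
        return paths


def generate_dataset(
    config: GeneratorConfig, cohort: CohortDefinition | None = None
) -> SyntheticDataset:
    """Generate the full linked bundle; every enrollment site has claims and
    every physician in the publications table appears in claims."""
    config.validate()
    cohort = cohort or default_cohort()
    sites = generate_sites(config)
    covariates = generate_site_covariates(config, sites)
    claims = generate_claims(config, sites, covariates, cohort)
    enrollment, ground_truth = generate_enrollment(config, sites, covariates)
    publications = _generate_publications(config, covariates, claims)
    trials = _generate_trials(config, covariates)
    return SyntheticDataset(
        config=config,
        cohort=cohort,
        sites=sites,
        covariates=covariates,
        claims=claims,
        enrollment=enrollment,
        publications=publications,
        trials=trials,
        ground_truth=ground_truth,
    )
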