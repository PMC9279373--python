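"""Synthetic EMR cohort generator with known ground-truth fasting behaviour.

Real fasting-verification studies never observe whether a patient actually
fasted; this module generates outpatient glucose / HbA1c laboratory tables in
which the truth is known, so every downstream stage (conditioning, labeling,
modelling, IGM reporting) can be validated end to end.

The generative model
--------------------
* Each patient has a diabetes (DM) status, demographics, home coordinates
  scattered around a single hospital with exponential distance decay, a
  clinic-division habit and comorbidity/medication onset dates.
* Per-sample HbA1c is drawn from DM-status-specific normals (defaults match
  the fasting-cohort moments: non-DM 5.86 (0.98) %, DM 7.59 (1.42) %),
  truncated at 3.5 %.
* Whether the patient truly fasted for a draw follows a logistic *adherence*
  model in the epidemiological covariates (age, sex, distance, DM, lipid
  co-testing, sampling timing, division).  Coefficients are expressed as
  log-odds of a NONFASTING draw, so exp(coefficient) is directly comparable
  to an odds-ratio table for nonfasting status.
* Glucose is anchored to the HbA1c-derived estimated average glucose (eAG):
  fasting draws fall a configurable offset below eAG, nonfasting draws above
  it, both truncated at 40 mg/dL.  This reproduces the characteristic bimodal
  picture (fasting peak just below 100 mg/dL, nonfasting peak above the
  126 mg/dL diagnostic cut) without claiming a particular postprandial
  dynamic.
* Conditioning noise is injected at configurable rates: order labels flipped
  to PC/random, "one-touch"/"bedside" annotations, same-day duplicate draws,
  nonnumeric / zero / >1000 mg/dL values, and non-outpatient settings.

All randomness flows through one :func:`numpy.random.default_rng` stream, so
a fixed seed yields byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

from fastlabel.fasting_labeler import EAG_INTERCEPT, EAG_SLOPE

__all__ = [
    "GeneratorConfig",
    "NoiseRates",
    "Cohort",
    "default_adherence_coefficients",
    "generate_cohort",
    "generate_preprocedure_subset",
    "write_cohort",
]

DIVISIONS = (
    "health_management_center",
    "general_medicine",
    "metabolism_endocrinology",
    "nephrology",
    "cardiology",
    "family_medicine",
    "surgery",
    "pediatrics",
    "chinese_medicine",
    "other",
)

# Division mix differs sharply by DM status (DM care concentrates in
# metabolism/endocrinology; health checks dominate the non-DM stream).
_DIVISION_P_NONDM = {
    "health_management_center": 0.292,
    "cardiology": 0.176,
    "general_medicine": 0.163,
    "metabolism_endocrinology": 0.120,
    "family_medicine": 0.091,
    "nephrology": 0.063,
    "surgery": 0.046,
    "chinese_medicine": 0.036,
    "pediatrics": 0.009,
    "other": 0.004,
}
_DIVISION_P_DM = {
    "metabolism_endocrinology": 0.552,
    "cardiology": 0.150,
    "nephrology": 0.087,
    "general_medicine": 0.083,
    "family_medicine": 0.066,
    "chinese_medicine": 0.030,
    "pediatrics": 0.015,
    "surgery": 0.012,
    "health_management_center": 0.003,
    "other": 0.002,
}

TIMING_BINS = ("07:00-12:59", "13:00-17:59", "18:00-22:59", "other")
_TIMING_P = (0.930, 0.055, 0.0115, 0.0035)
_TIMING_HOURS = {
    "07:00-12:59": (7, 13),
    "13:00-17:59": (13, 18),
    "18:00-22:59": (18, 23),
    "other": (0, 7),
}

NONFASTING_TAGS = ("one_touch", "bedside_check", "pc_note")

_KM_PER_DEG = 111.19492664455873  # (pi/180) * 6371.0088


def default_adherence_coefficients() -> dict[str, float]:
    """Default adherence-model coefficients (log-odds of a nonfasting draw).

    Effect sizes follow a published odds-ratio structure for nonfasting
    status: age 1.05 per 5 y, male 1.16, distance 0.998 per 10 km, sampling
    after noon protective, all clinical divisions roughly twice the odds of
    the health-management-center reference, and DM (0.70) / concomitant
    lipid testing (0.78) protective.  The intercept is set so that roughly
    half of all draws are nonfasting under the default covariate mix.
    """
    log = np.log
    coef = {
        "intercept": -1.10,
        "age_per5": log(1.05),
        "male": log(1.16),
        "distance_per10": log(0.998),
        "dm": log(0.70),
        "lipid_test": log(0.78),
        "timing_13:00-17:59": log(0.87),
        "timing_18:00-22:59": log(0.78),
        "timing_other": 0.0,
        "division_general_medicine": log(2.24),
        "division_metabolism_endocrinology": log(2.11),
        "division_nephrology": log(2.38),
        "division_cardiology": log(1.99),
        "division_family_medicine": log(1.90),
        "division_surgery": log(1.74),
        "division_pediatrics": log(1.78),
        "division_chinese_medicine": log(1.86),
        "division_other": log(1.95),
    }
    return {k: float(v) for k, v in coef.items()}


@dataclass
class NoiseRates:
    """Per-record probabilities of conditioning-rule noise."""

    label_pc_or_random: float = 0.02
    annotation_nonfasting: float = 0.02
    same_day_duplicate: float = 0.01
    nonnumeric: float = 0.005
    zero: float = 0.003
    gt_1000: float = 0.002
    non_outpatient: float = 0.05

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"noise rate {f.name!r} must be in [0, 1], got {v}")

    @property
    def all_zero(self) -> bool:
        return all(getattr(self, f.name) == 0 for f in dataclasses.fields(self))


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Parameters
    ----------
    n_patients : int
        Number of patients to simulate.
    seed : int
        Seed for the single RNG stream; fixed seed implies byte-identical
        output.
    dm_prevalence : float
        Fraction of patients ever diagnosed with type 2 DM (default 0.292).
    hba1c_* : float
        DM-status-specific HbA1c normal parameters in % units, truncated
        at 3.5 %.
    fasting_offset_mgdl, fasting_sd_mgdl : float
        Fasting glucose ~ Normal(eAG − offset, sd), truncated at 40 mg/dL.
    nonfasting_offset_mgdl, nonfasting_sd_mgdl : float
        Nonfasting glucose ~ Normal(eAG + offset, sd), truncated at 40 mg/dL.
    adherence_coefficients : dict
        Log-odds of a nonfasting draw per covariate; see
        :func:`default_adherence_coefficients`.
    noise_rates : NoiseRates
        Conditioning-noise probabilities.
    hba1c_pair_probability : float
        Probability that a glucose draw has a same-day HbA1c record.
    mean_samples_per_patient : float
        Mean glucose draws per patient (>= 1; 1 + Poisson(mean − 1)).
    period_range : (int, int)
        First and last calendar year covered (inclusive).
    incident_dm_fraction : float
        Among DM patients, fraction whose diagnosis date falls inside the
        study period rather than before it (drives the IGM statistic).
    """

    n_patients: int = 2000
    seed: int = 0
    dm_prevalence: float = 0.292
    hba1c_nondm_mean: float = 5.86
    hba1c_nondm_sd: float = 0.98
    hba1c_dm_mean: float = 7.59
    hba1c_dm_sd: float = 1.42
    fasting_offset_mgdl: float = 25.0
    fasting_sd_mgdl: float = 15.0
    nonfasting_offset_mgdl: float = 30.0
    nonfasting_sd_mgdl: float = 35.0
    adherence_coefficients: dict[str, float] = field(
        default_factory=default_adherence_coefficients
    )
    noise_rates: NoiseRates = field(default_factory=NoiseRates)
    hba1c_pair_probability: float = 0.9
    mean_samples_per_patient: float = 2.0
    period_range: tuple[int, int] = (2003, 2018)
    incident_dm_fraction: float = 0.2
    male_fraction: float = 0.53
    age_mean: float = 57.0
    age_sd: float = 15.0
    hospital_lat: float = 24.16
    hospital_lon: float = 120.68
    mean_distance_km: float = 12.0
    lipid_test_probability: float = 0.70
    glucose_truncation_mgdl: float = 40.0
    hba1c_truncation_pct: float = 3.5

    def __post_init__(self) -> None:
        if isinstance(self.noise_rates, dict):
            self.noise_rates = NoiseRates(**self.noise_rates)
        if isinstance(self.period_range, list):
            self.period_range = tuple(self.period_range)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "dm_prevalence",
            "hba1c_pair_probability",
            "incident_dm_fraction",
            "male_fraction",
            "lipid_test_probability",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"probability {name!r} must be in [0, 1], got {v}")
        for name in (
            "hba1c_nondm_sd",
            "hba1c_dm_sd",
            "fasting_sd_mgdl",
            "nonfasting_sd_mgdl",
            "age_sd",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"standard deviation {name!r} must be > 0, got {v}")
        if self.mean_samples_per_patient < 1:
            raise ValueError("mean_samples_per_patient must be >= 1")
        if self.period_range[0] > self.period_range[1]:
            raise ValueError("period_range must be (first_year, last_year)")
        self.noise_rates.validate()

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_range"] = list(self.period_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


class Cohort(NamedTuple):
    """The four generated tables."""

    patients: pd.DataFrame
    glucose: pd.DataFrame
    hba1c: pd.DataFrame
    truth: pd.DataFrame


def _truncnorm(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _scatter_homes(rng, n, cfg: GeneratorConfig):
    """Home coordinates around the hospital with exponential distance decay."""
    dist = rng.exponential(cfg.mean_distance_km, n)
    bearing = rng.uniform(0, 2 * np.pi, n)
    lat = cfg.hospital_lat + (dist / _KM_PER_DEG) * np.cos(bearing)
    lon = cfg.hospital_lon + (
        dist / (_KM_PER_DEG * np.cos(np.radians(cfg.hospital_lat)))
    ) * np.sin(bearing)
    return np.clip(lat, -90, 90), np.clip(lon, -180, 180)


def _haversine_km(lat1, lon1, lat2, lon2):
    # local copy to avoid a circular import with cohort_features
    r = 6371.0088
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(a))


def _generate_patients(rng, cfg: GeneratorConfig) -> pd.DataFrame:
    n = cfg.n_patients
    start = pd.Timestamp(f"{cfg.period_range[0]}-01-01")
    end = pd.Timestamp(f"{cfg.period_range[1]}-12-31")
    span_days = (end - start).days

    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    age0 = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 20, 95)
    birth = start - pd.to_timedelta(np.round(age0 * 365.25), unit="D")

    dm = rng.random(n) < cfg.dm_prevalence
    incident = dm & (rng.random(n) < cfg.incident_dm_fraction)
    onset_days = np.where(
        incident,
        rng.integers(0, span_days + 1, n),
        -rng.integers(1, int(5 * 365.25), n),
    )
    dm_onset = pd.Series(start + pd.to_timedelta(onset_days, unit="D")).where(
        pd.Series(dm), pd.NaT
    )

    def _onset(p):
        has = rng.random(n) < p
        days = rng.integers(-int(10 * 365.25), span_days + 1, n)
        return pd.Series(start + pd.to_timedelta(days, unit="D")).where(
            pd.Series(has), pd.NaT
        )

    division = np.empty(n, dtype=object)
    for mask, probs in ((~dm, _DIVISION_P_NONDM), (dm, _DIVISION_P_DM)):
        k = int(mask.sum())
        if k:
            levels = list(probs)
            p = np.array([probs[v] for v in levels])
            division[mask] = rng.choice(levels, size=k, p=p / p.sum())

    lat, lon = _scatter_homes(rng, n, cfg)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "sex": sex,
            "birth_date": birth.normalize(),
            "home_lat": np.round(lat, 6),
            "home_lon": np.round(lon, 6),
            "dm_onset_date": pd.to_datetime(dm_onset.values).normalize(),
            "hypertension_onset": pd.to_datetime(_onset(0.40).values).normalize(),
            "cad_onset": pd.to_datetime(_onset(0.15).values).normalize(),
            "stroke_onset": pd.to_datetime(_onset(0.10).values).normalize(),
            "statin_start": pd.to_datetime(_onset(0.25).values).normalize(),
            "division_habit": division,
        }
    )


def _nonfasting_logit(cfg, age_per5, male, dist_per10, dm, lipid, timing, division):
    c = cfg.adherence_coefficients
    logit = (
        c["intercept"]
        + c["age_per5"] * age_per5
        + c["male"] * male
        + c["distance_per10"] * dist_per10
        + c["dm"] * dm
        + c["lipid_test"] * lipid
    )
    for t in TIMING_BINS[1:]:
        logit = logit + c.get(f"timing_{t}", 0.0) * (timing == t)
    for d in DIVISIONS:
        if d == "health_management_center":
            continue
        logit = logit + c.get(f"division_{d}", 0.0) * (division == d)
    return logit


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate the four EMR-style tables (patients, glucose, hba1c, truth).

    Deterministic given ``config.seed``.  Each glucose record has exactly one
    truth row keyed by ``sample_id`` (= ``record_id``); truth never flows
    into the modelling feature path.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _generate_patients(rng, config)

    start = pd.Timestamp(f"{config.period_range[0]}-01-01")
    end = pd.Timestamp(f"{config.period_range[1]}-12-31")
    span_days = (end - start).days

    n_samp = 1 + rng.poisson(config.mean_samples_per_patient - 1.0, config.n_patients)
    idx = np.repeat(np.arange(config.n_patients), n_samp)
    m = idx.size

    pat = patients.iloc[idx].reset_index(drop=True)
    day = rng.integers(0, span_days + 1, m)
    coll_date = start + pd.to_timedelta(day, unit="D")

    timing = rng.choice(np.array(TIMING_BINS, dtype=object), size=m, p=_TIMING_P)
    hour = np.empty(m, dtype=int)
    for t, (lo, hi) in _TIMING_HOURS.items():
        mask = timing == t
        hour[mask] = rng.integers(lo, hi, int(mask.sum()))
    minute = rng.integers(0, 60, m)
    coll_dt = coll_date + pd.to_timedelta(hour * 60 + minute, unit="m")

    interval = np.round(rng.gamma(1.2, 30.0, m)).astype(int)
    request_date = (coll_dt - pd.to_timedelta(interval, unit="D")).normalize()
    visits = rng.negative_binomial(2, 2.0 / 14.0, m)
    lipid = rng.random(m) < config.lipid_test_probability
    dm_at = (pat["dm_onset_date"].values <= coll_date.values) & pd.notna(
        pat["dm_onset_date"].values
    )

    a1c_mean = np.where(dm_at, config.hba1c_dm_mean, config.hba1c_nondm_mean)
    a1c_sd = np.where(dm_at, config.hba1c_dm_sd, config.hba1c_nondm_sd)
    a1c = np.round(
        _truncnorm(rng, a1c_mean, a1c_sd, config.hba1c_truncation_pct, m), 1
    )
    eag = EAG_SLOPE * a1c + EAG_INTERCEPT

    age_at = (coll_date - pd.DatetimeIndex(pat["birth_date"])).days / 365.25
    dist_km = _haversine_km(
        pat["home_lat"].values,
        pat["home_lon"].values,
        config.hospital_lat,
        config.hospital_lon,
    )
    male = (pat["sex"] == "male").to_numpy()
    division = pat["division_habit"].to_numpy()

    logit = _nonfasting_logit(
        config, age_at / 5.0, male, dist_km / 10.0, dm_at, lipid, timing, division
    )
    p_nonfasting = expit(np.asarray(logit, dtype=float))
    truly_fasted = rng.random(m) >= p_nonfasting

    mean_f = eag - config.fasting_offset_mgdl
    mean_nf = eag + config.nonfasting_offset_mgdl
    glucose = np.where(
        truly_fasted,
        _truncnorm(rng, mean_f, config.fasting_sd_mgdl, config.glucose_truncation_mgdl, m),
        _truncnorm(
            rng, mean_nf, config.nonfasting_sd_mgdl, config.glucose_truncation_mgdl, m
        ),
    )
    glucose = np.round(glucose).astype(int)

    record_id = np.array([f"G{i:08d}" for i in range(m)], dtype=object)
    glucose_df = pd.DataFrame(
        {
            "record_id": record_id,
            "sample_id": record_id,
            "patient_id": pat["patient_id"].to_numpy(),
            "request_date": request_date,
            "collection_datetime": coll_dt,
            "raw_value": glucose.astype(str),
            "order_label": "AC",
            "annotations": "",
            "setting": "outpatient",
            "division": division,
            "prior_year_visits": visits,
            "lipid_same_day": lipid,
        }
    )

    truth_df = pd.DataFrame(
        {
            "sample_id": record_id,
            "truly_fasted": truly_fasted,
            "adherence_probability": np.round(1.0 - p_nonfasting, 6),
        }
    )

    glucose_df, truth_df = _inject_noise(rng, config, glucose_df, truth_df)

    # same-day HbA1c records, deduplicated per patient-day
    has_a1c = rng.random(m) < config.hba1c_pair_probability
    hba1c_df = pd.DataFrame(
        {
            "patient_id": pat.loc[has_a1c, "patient_id"].to_numpy(),
            "collection_date": coll_date[has_a1c].normalize(),
            "hba1c_pct": a1c[has_a1c],
        }
    )
    hba1c_df = (
        hba1c_df.drop_duplicates(["patient_id", "collection_date"])
        .sort_values(["patient_id", "collection_date"])
        .reset_index(drop=True)
    )
    hba1c_df.insert(0, "hba1c_id", [f"H{i:08d}" for i in range(len(hba1c_df))])

    glucose_df = glucose_df.sort_values(
        ["patient_id", "collection_datetime", "record_id"]
    ).reset_index(drop=True)
    truth_df = (
        truth_df.set_index("sample_id")
        .loc[glucose_df["sample_id"]]
        .reset_index()
    )
    return Cohort(patients, glucose_df, hba1c_df, truth_df)


def _inject_noise(rng, config: GeneratorConfig, glucose: pd.DataFrame, truth):
    nr = config.noise_rates
    m = len(glucose)
    if nr.all_zero:
        return glucose, truth
    glucose = glucose.copy()

    flip = rng.random(m) < nr.label_pc_or_random
    glucose.loc[flip, "order_label"] = rng.choice(
        np.array(["PC", "random"], dtype=object), size=int(flip.sum())
    )
    annot = rng.random(m) < nr.annotation_nonfasting
    glucose.loc[annot, "annotations"] = rng.choice(
        np.array(NONFASTING_TAGS, dtype=object), size=int(annot.sum())
    )
    nonout = rng.random(m) < nr.non_outpatient
    glucose.loc[nonout, "setting"] = rng.choice(
        np.array(["inpatient", "emergency"], dtype=object), size=int(nonout.sum())
    )

    # value corruptions are mutually exclusive per record
    r = rng.random(m)
    bad_txt = r < nr.nonnumeric
    bad_zero = (r >= nr.nonnumeric) & (r < nr.nonnumeric + nr.zero)
    bad_big = (r >= nr.nonnumeric + nr.zero) & (
        r < nr.nonnumeric + nr.zero + nr.gt_1000
    )
    glucose.loc[bad_txt, "raw_value"] = rng.choice(
        np.array(["N/A", "not measured", "ERR"], dtype=object), size=int(bad_txt.sum())
    )
    glucose.loc[bad_zero, "raw_value"] = "0"
    glucose.loc[bad_big, "raw_value"] = rng.integers(
        1001, 2500, int(bad_big.sum())
    ).astype(str)

    # same-day duplicate draws ~2 h later (clamped to the same calendar day);
    # the repeat draw is taken after possible food intake, hence nonfasting.
    dup = rng.random(m) < nr.same_day_duplicate
    if dup.any():
        d = glucose.loc[dup].copy()
        day_end = d["collection_datetime"].dt.normalize() + pd.Timedelta(
            hours=23, minutes=59
        )
        d["collection_datetime"] = np.minimum(
            d["collection_datetime"] + pd.Timedelta(hours=2), day_end
        )
        d["record_id"] = d["record_id"] + "D"
        d["sample_id"] = d["record_id"]
        d["raw_value"] = rng.integers(90, 320, len(d)).astype(str)
        tdup = truth.loc[dup.nonzero()[0]].copy()
        tdup["sample_id"] = d["sample_id"].to_numpy()
        tdup["truly_fasted"] = False
        glucose = pd.concat([glucose, d], ignore_index=True)
        truth = pd.concat([truth, tdup], ignore_index=True)
    return glucose, truth


def generate_preprocedure_subset(
    config: GeneratorConfig, n: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``n`` known-fasting glucose+HbA1c pairs.

    Emulates a validation set of morning fasting samples drawn before a
    scheduled procedure: every truth record is truly fasted and glucose is
    drawn from the fasting model only.  Returns ``(pairs, truth)`` where
    pairs has columns sample_id, patient_id, glucose_mgdl, hba1c_pct,
    dm_status.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    config.validate()
    rng = np.random.default_rng([config.seed, 0xFA57])
    dm = rng.random(n) < config.dm_prevalence
    a1c_mean = np.where(dm, config.hba1c_dm_mean, config.hba1c_nondm_mean)
    a1c_sd = np.where(dm, config.hba1c_dm_sd, config.hba1c_nondm_sd)
    a1c = np.round(_truncnorm(rng, a1c_mean, a1c_sd, config.hba1c_truncation_pct, n), 1)
    eag = EAG_SLOPE * a1c + EAG_INTERCEPT
    glucose = np.round(
        _truncnorm(
            rng,
            eag - config.fasting_offset_mgdl,
            config.fasting_sd_mgdl,
            config.glucose_truncation_mgdl,
            n,
        )
    ).astype(int)
    sid = [f"E{i:07d}" for i in range(n)]
    pairs = pd.DataFrame(
        {
            "sample_id": sid,
            "patient_id": [f"PE{i:06d}" for i in range(n)],
            "glucose_mgdl": glucose.astype(float),
            "hba1c_pct": a1c,
            "dm_status": dm,
        }
    )
    truth = pd.DataFrame(
        {
            "sample_id": sid,
            "truly_fasted": np.ones(n, dtype=bool),
            "adherence_probability": np.ones(n),
        }
    )
    return pairs, truth


def write_cohort(cohort: Cohort, outdir: str | Path, config: GeneratorConfig) -> None:
    """Write the four CSV tables plus a JSON sidecar with the full config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(outdir / "patients.csv", index=False)
    cohort.glucose.to_csv(outdir / "glucose.csv", index=False)
    cohort.hba1c.to_csv(outdir / "hba1c.csv", index=False)
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
    with open(outdir / "generator_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
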