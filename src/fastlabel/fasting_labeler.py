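"""HbA1c-anchored theoretical fasting labels for ontological fasting glucose.

A glucose value drawn after an overnight fast should lie below the patient's
average glycaemia; the HbA1c-derived estimated average glucose (eAG, here
``ac_average``) therefore acts as a theoretical upper limit of a true
fasting value.  Three criteria assign a *theoretical fasting* label to each
same-day glucose+HbA1c pair:

1. non-DM, HbA1c < 5.5 %:   fasting iff glucose < 100 mg/dL;
2. non-DM, 5.5 ≤ HbA1c < 6.5 %:  fasting iff glucose < eAG − 1 SD of the
   ontological-fasting glucose distribution (``sd_reference``);
3. DM (any HbA1c):          fasting iff glucose < eAG.

All comparisons are strict.  Non-DM patients with HbA1c ≥ 6.5 % fall outside
the three bands; they are labeled with the criterion-3 rule form
(glucose < eAG) and flagged (``offband``) for auditing, since eAG as an
upper fasting limit applies regardless of diagnosis status.

eAG uses the linear regression of average glucose on HbA1c,
``eAG = 28.7·A1c − 46.7`` (mg/dL), configurable for other unit systems.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EAG_SLOPE",
    "EAG_INTERCEPT",
    "LabelerConfig",
    "estimate_average_glucose",
    "compute_sd_reference",
    "label_theoretical_fasting",
    "label_cohort",
    "validate_against_truth",
]

EAG_SLOPE = 28.7  # mg/dL per % HbA1c
EAG_INTERCEPT = -46.7  # mg/dL


@dataclass
class LabelerConfig:
    """Thresholds of the three fasting criteria.

    ``sd_reference`` is the 1-SD term of criterion 2: if ``None`` it is
    computed from the cohort being labeled (non-DM stratum of the
    ontological glucose values, sample SD); a float fixes it explicitly.
    """

    eag_slope: float = EAG_SLOPE
    eag_intercept: float = EAG_INTERCEPT
    nondm_low_a1c_cut: float = 5.5
    nondm_high_a1c_cut: float = 6.5
    fasting_cut_low_a1c: float = 100.0
    sd_reference: float | None = None
    dm_fbg_diag_cut: float = 126.0

    def __post_init__(self) -> None:
        if not self.eag_slope > 0:
            raise ValueError("eag_slope must be > 0")
        if not self.nondm_low_a1c_cut < self.nondm_high_a1c_cut:
            raise ValueError("HbA1c cuts must be strictly ordered")
        if self.sd_reference is not None and not self.sd_reference >= 0:
            raise ValueError("sd_reference must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def estimate_average_glucose(hba1c_pct, config: LabelerConfig | None = None):
    """Estimated average glucose (mg/dL) from HbA1c (%).

    Strictly increasing linear map ``slope·A1c + intercept``.  Accepts a
    scalar or array; raises ``ValueError`` on nonpositive input.
    """
    config = config or LabelerConfig()
    a1c = np.asarray(hba1c_pct, dtype=float)
    if np.any(a1c <= 0):
        raise ValueError("HbA1c must be > 0 %")
    out = config.eag_slope * a1c + config.eag_intercept
    return float(out) if np.isscalar(hba1c_pct) else out


def compute_sd_reference(values: Iterable[float], ddof: int = 1) -> float:
    """Sample standard deviation (n−1 denominator) of a glucose stratum."""
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError(
            "need at least 2 values to estimate sd_reference; "
            "pass an explicit sd_reference instead"
        )
    return float(np.std(v, ddof=ddof))


def _thresholds(a1c, dm, config: LabelerConfig, sd_reference: float):
    """Per-sample fasting threshold, criterion id and off-band flag."""
    eag = config.eag_slope * a1c + config.eag_intercept
    crit1 = ~dm & (a1c < config.nondm_low_a1c_cut)
    crit2 = ~dm & (a1c >= config.nondm_low_a1c_cut) & (a1c < config.nondm_high_a1c_cut)
    offband = ~dm & (a1c >= config.nondm_high_a1c_cut)
    thr = np.where(
        crit1,
        config.fasting_cut_low_a1c,
        np.where(crit2, eag - sd_reference, eag),
    )
    criterion = np.where(crit1, 1, np.where(crit2, 2, 3))
    return thr, criterion, offband, eag


def label_theoretical_fasting(
    glucose_mgdl,
    hba1c_pct,
    dm_status,
    config: LabelerConfig | None = None,
    sd_reference: float | None = None,
):
    """Apply the three fasting criteria to one sample or to arrays.

    Parameters
    ----------
    glucose_mgdl, hba1c_pct, dm_status
        Scalars or equal-length arrays.
    sd_reference
        The 1-SD term of criterion 2; overrides ``config.sd_reference``.
        Required (here or in the config) whenever criterion 2 applies.

    Returns
    -------
    (theoretical_fasting, criterion)
        Booleans and criterion ids in {1, 2, 3}; scalars in, scalars out.
    """
    config = config or LabelerConfig()
    scalar = np.isscalar(glucose_mgdl)
    g = np.atleast_1d(np.asarray(glucose_mgdl, dtype=float))
    a1c = np.atleast_1d(np.asarray(hba1c_pct, dtype=float))
    dm = np.atleast_1d(np.asarray(dm_status, dtype=bool))
    if np.any(a1c <= 0):
        raise ValueError("HbA1c must be > 0 %")
    sd = sd_reference if sd_reference is not None else config.sd_reference
    crit2_present = np.any(
        ~dm & (a1c >= config.nondm_low_a1c_cut) & (a1c < config.nondm_high_a1c_cut)
    )
    if sd is None:
        if crit2_present:
            raise ValueError(
                "sd_reference is required when criterion 2 applies; "
                "set it in LabelerConfig or pass it explicitly"
            )
        sd = 0.0
    thr, criterion, _, _ = _thresholds(a1c, dm, config, sd)
    fasting = g < thr  # strict everywhere
    if scalar:
        return bool(fasting[0]), int(criterion[0])
    return fasting, criterion


def label_cohort(
    conditioned: pd.DataFrame,
    hba1c: pd.DataFrame,
    patients: pd.DataFrame,
    config: LabelerConfig | None = None,
    sd_mode: str = "cohort",
) -> tuple[pd.DataFrame, float]:
    """Label a conditioned glucose table against same-day HbA1c records.

    Parameters
    ----------
    conditioned
        AC_ontological records (output of glucose conditioning) with
        ``patient_id``, ``collection_datetime`` and ``value_mgdl``.
    hba1c
        HbA1c table with ``patient_id``, ``collection_date``, ``hba1c_pct``.
    patients
        Patient table with ``dm_onset_date`` (NaT if never diagnosed); DM
        status at sampling is onset on/before the collection date.
    sd_mode
        ``"cohort"`` computes ``sd_reference`` as the sample SD of the
        non-DM stratum of this cohort's ontological glucose values;
        ``"fixed"`` uses ``config.sd_reference``.

    Returns
    -------
    (labeled, sd_reference)
        ``labeled`` has one row per input record.  Records without a
        same-day HbA1c are retained with ``labelable == False`` and missing
        label/criterion (unlabelable, *not* nonfasting).
    """
    config = config or LabelerConfig()
    if sd_mode not in ("cohort", "fixed"):
        raise ValueError("sd_mode must be 'cohort' or 'fixed'")

    df = conditioned.copy()
    df["collection_date"] = pd.to_datetime(df["collection_datetime"]).dt.normalize()
    a1c = hba1c[["patient_id", "collection_date", "hba1c_pct"]].copy()
    a1c["collection_date"] = pd.to_datetime(a1c["collection_date"]).dt.normalize()
    a1c = a1c.drop_duplicates(["patient_id", "collection_date"])
    df = df.merge(a1c, on=["patient_id", "collection_date"], how="left")

    onset = patients.set_index("patient_id")["dm_onset_date"]
    onset = pd.to_datetime(onset.reindex(df["patient_id"]).to_numpy())
    df["dm_status"] = pd.notna(onset) & (onset <= df["collection_date"].to_numpy())

    labelable = df["hba1c_pct"].notna().to_numpy()
    if sd_mode == "fixed":
        if config.sd_reference is None:
            raise ValueError("sd_mode='fixed' requires config.sd_reference")
        sd_ref = float(config.sd_reference)
    else:
        stratum = df.loc[labelable & ~df["dm_status"], "value_mgdl"]
        sd_ref = (
            compute_sd_reference(stratum.to_numpy())
            if stratum.size >= 2
            else (config.sd_reference if config.sd_reference is not None else 0.0)
        )

    g = df["value_mgdl"].to_numpy(dtype=float)
    a1cv = df["hba1c_pct"].to_numpy(dtype=float)
    dm = df["dm_status"].to_numpy(dtype=bool)
    thr, criterion, offband, eag = _thresholds(
        np.where(labelable, a1cv, 1.0), dm, config, sd_ref
    )

    df["ac_average"] = np.where(labelable, eag, np.nan)
    df["labelable"] = labelable
    df["criterion"] = pd.array(
        np.where(labelable, criterion, -1), dtype="Int64"
    )
    df.loc[~labelable, "criterion"] = pd.NA
    fasting = pd.array(g < thr, dtype="boolean")
    fasting[~labelable] = pd.NA
    df["theoretical_fasting"] = fasting
    df["offband_nondm_high_a1c"] = offband & labelable
    df["glucose_mgdl"] = g
    return df, sd_ref


def validate_against_truth(
    labeled: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """Confusion of theoretical labels against ground-truth fasting status.

    Joins on ``sample_id``; raises on ids missing from the truth table.
    Percentages are rounded to 2 decimals (e.g. 314 of 4519 → 6.95).
    """
    if "sample_id" not in labeled.columns or "sample_id" not in truth.columns:
        raise KeyError("both tables need a 'sample_id' column")
    t = truth.set_index("sample_id")["truly_fasted"]
    missing = labeled.loc[~labeled["sample_id"].isin(t.index), "sample_id"]
    if len(missing):
        raise KeyError(
            f"{len(missing)} sample ids missing from truth table: "
            f"{missing.head(10).tolist()}"
        )
    lab = labeled[labeled["labelable"]] if "labelable" in labeled.columns else labeled
    truly = t.loc[lab["sample_id"]].to_numpy(dtype=bool)
    pred_fast = lab["theoretical_fasting"].to_numpy(dtype=bool)

    n_fasted = int(truly.sum())
    n_nonfasted = int((~truly).sum())
    fn = int((truly & ~pred_fast).sum())  # truly fasted, labeled nonfasting
    fp = int((~truly & pred_fast).sum())  # truly nonfasted, labeled fasting
    return {
        "n": int(len(lab)),
        "n_truly_fasted": n_fasted,
        "fasted_labeled_nonfasting": fn,
        "fasted_labeled_nonfasting_pct": round(100.0 * fn / n_fasted, 2)
        if n_fasted
        else float("nan"),
        "n_truly_nonfasted": n_nonfasted,
        "nonfasted_labeled_fasting": fp,
        "nonfasted_labeled_fasting_pct": round(100.0 * fp / n_nonfasted, 2)
        if n_nonfasted
        else float("nan"),
    }
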