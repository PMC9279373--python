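"""Covariate extraction, balanced curation and stratified splitting.

Builds the modelling dataset for nonfasting-status prediction.  The core
("model-2") covariates use the epidemiological scalings that make odds
ratios readable: glucose per 5 mg/dL, age per 5 years, request-to-sampling
interval per 28 days, prior-year outpatient visits per 4 visits, and
home-to-hospital distance per 10 km.  Scaled features are exact affine
transforms of the raw quantities; missingness is preserved, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM",
    "TIMING_BINS",
    "MODEL2_FEATURES",
    "SplitSpec",
    "haversine_km",
    "timing_bin_of",
    "build_features",
    "curate_balanced",
    "split_train_test",
]

EARTH_RADIUS_KM = 6371.0088

TIMING_BINS = ("07:00-12:59", "13:00-17:59", "18:00-22:59", "other")

#: The hard-coded parsimonious covariate set (14 variables; categorical
#: timing/division expand to reference-coded dummies at fit time).
MODEL2_FEATURES = (
    "glucose_per5",
    "age_per5",
    "male",
    "timing_bin",
    "interval_per28",
    "visits_per4",
    "distance_per10",
    "division",
    "hypertension",
    "dm",
    "cad",
    "stroke",
    "statin_use",
    "concomitant_lipid_test",
)


@dataclass
class SplitSpec:
    """Stratified train/test split specification."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify_on: str = "label_nonfasting"

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance (km) on a sphere of radius 6371.0088 km.

    Vectorized; raises on out-of-range coordinates.  Symmetric, zero iff
    the points coincide, and satisfies the triangle inequality.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in
                              (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat[np.isfinite(lat)]) > 90):
            raise ValueError("latitude out of range [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon[np.isfinite(lon)]) > 180):
            raise ValueError("longitude out of range [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if d.ndim == 0 else d


def timing_bin_of(collection_datetime) -> pd.Series:
    """Assign the sampling-timing bin from the collection time of day."""
    dt = pd.to_datetime(pd.Series(collection_datetime))
    h = dt.dt.hour
    out = pd.Series(np.select(
        [(h >= 7) & (h < 13), (h >= 13) & (h < 18), (h >= 18) & (h < 23)],
        TIMING_BINS[:3],
        default="other",
    ), index=dt.index, dtype=object)
    return out


def _count_prior_year_visits(samples: pd.DataFrame, visits: pd.DataFrame) -> np.ndarray:
    """Visits in the 365-day half-open window ending the day before sampling."""
    v = visits.copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"]).dt.normalize()
    counts = np.zeros(len(samples), dtype=float)
    grouped = {pid: np.sort(g["visit_date"].to_numpy())
               for pid, g in v.groupby("patient_id")}
    days = pd.to_datetime(samples["collection_datetime"]).dt.normalize().to_numpy()
    for i, (pid, day) in enumerate(zip(samples["patient_id"].to_numpy(), days)):
        dates = grouped.get(pid)
        if dates is None:
            continue
        lo = np.searchsorted(dates, day - np.timedelta64(365, "D"), side="left")
        hi = np.searchsorted(dates, day, side="left")  # excludes sampling day
        counts[i] = hi - lo
    return counts


def build_features(
    labeled: pd.DataFrame,
    patients: pd.DataFrame,
    visits: pd.DataFrame | None = None,
    lipid_orders: pd.DataFrame | None = None,
    hospital_lat: float | None = None,
    hospital_lon: float | None = None,
    require_label: bool = True,
) -> pd.DataFrame:
    """Build one feature row per labeled sample.

    Parameters
    ----------
    labeled
        Output of :func:`fastlabel.fasting_labeler.label_cohort` (carries
        glucose, timestamps, division, DM status and the theoretical label).
    patients
        Patient table (birth date, sex, coordinates, comorbidity onsets).
    visits, lipid_orders
        Optional event tables.  If ``visits`` (patient_id, visit_date) is
        given, the prior-year count uses a 365-day half-open window ending
        the day before sampling; otherwise a pre-aggregated
        ``prior_year_visits`` column on ``labeled`` is used.  Same pattern
        for lipid orders vs a ``lipid_same_day`` column.
    hospital_lat, hospital_lon
        Hospital coordinates for the distance feature.  If omitted, the
        distance is missing (never silently zero).
    require_label
        Drop rows without a theoretical label (default).  With ``False``
        the rows are kept with a missing label, e.g. for scoring.

    Missing home coordinates leave the distance missing and are logged.
    """
    df = labeled.copy()
    if require_label:
        n0 = len(df)
        df = df[df["labelable"]].copy() if "labelable" in df.columns else df
        if len(df) < n0:
            logger.info("dropped %d unlabelable rows (no same-day HbA1c)",
                        n0 - len(df))

    p = patients.set_index("patient_id")
    pat = p.reindex(df["patient_id"])
    day = pd.to_datetime(df["collection_datetime"]).dt.normalize().to_numpy()

    age_years = (
        day - pd.to_datetime(pat["birth_date"]).to_numpy()
    ) / np.timedelta64(1, "D") / 365.25

    if hospital_lat is not None and hospital_lon is not None:
        lat = pat["home_lat"].to_numpy(dtype=float)
        lon = pat["home_lon"].to_numpy(dtype=float)
        missing = ~(np.isfinite(lat) & np.isfinite(lon))
        dist = np.full(len(df), np.nan)
        if (~missing).any():
            dist[~missing] = haversine_km(
                lat[~missing], lon[~missing], hospital_lat, hospital_lon
            )
        if missing.any():
            logger.warning("%d samples lack home coordinates; distance left "
                           "missing", int(missing.sum()))
    else:
        dist = np.full(len(df), np.nan)

    interval_days = (
        day - pd.to_datetime(df["request_date"]).to_numpy()
    ) / np.timedelta64(1, "D")

    if visits is not None:
        visit_counts = _count_prior_year_visits(df, visits)
    elif "prior_year_visits" in df.columns:
        visit_counts = df["prior_year_visits"].to_numpy(dtype=float)
    else:
        visit_counts = np.full(len(df), np.nan)

    if lipid_orders is not None:
        lo = lipid_orders.copy()
        lo["collection_date"] = pd.to_datetime(lo["collection_date"]).dt.normalize()
        key = set(zip(lo["patient_id"], lo["collection_date"]))
        lipid = np.fromiter(
            ((pid, d) in key for pid, d in zip(df["patient_id"].to_numpy(), day)),
            dtype=bool, count=len(df),
        )
    elif "lipid_same_day" in df.columns:
        lipid = df["lipid_same_day"].to_numpy(dtype=bool)
    else:
        lipid = np.zeros(len(df), dtype=bool)

    def _active(col: str) -> np.ndarray:
        if col not in pat.columns:
            return np.zeros(len(df), dtype=bool)
        onset = pd.to_datetime(pat[col]).to_numpy()
        return pd.notna(onset) & (onset <= day)

    label = df["theoretical_fasting"]
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].to_numpy()
            if "sample_id" in df.columns else df["record_id"].to_numpy(),
            "patient_id": df["patient_id"].to_numpy(),
            "label_nonfasting": pd.array(
                [pd.NA if pd.isna(v) else (not v) for v in label], dtype="boolean"
            ),
            "glucose_per5": df["value_mgdl"].to_numpy(dtype=float) / 5.0,
            "age_per5": age_years / 5.0,
            "male": (pat["sex"].to_numpy() == "male"),
            "timing_bin": timing_bin_of(df["collection_datetime"]).to_numpy(),
            "interval_per28": interval_days / 28.0,
            "visits_per4": visit_counts / 4.0,
            "distance_per10": dist / 10.0,
            "division": df["division"].to_numpy(),
            "hypertension": _active("hypertension_onset"),
            "dm": df["dm_status"].to_numpy(dtype=bool),
            "cad": _active("cad_onset"),
            "stroke": _active("stroke_onset"),
            "statin_use": _active("statin_start"),
            "concomitant_lipid_test": lipid,
        }
    )
    bad_interval = out["interval_per28"] < 0
    if bad_interval.any():
        logger.warning("%d samples have negative request-to-sampling intervals",
                       int(bad_interval.sum()))
    return out.reset_index(drop=True)


def curate_balanced(
    features: pd.DataFrame,
    seed: int,
    one_per_patient: bool = True,
    label_col: str = "label_nonfasting",
) -> pd.DataFrame:
    """Curate an exact 1:1 dataset by undersampling the majority class.

    With ``one_per_patient`` (default) only each patient's first qualifying
    sample enters, which prevents patient leakage across later splits.  The
    majority class is then randomly undersampled without replacement to the
    minority count.  Deterministic given ``seed``.
    """
    df = features[features[label_col].notna()].copy()
    if one_per_patient:
        df = df.drop_duplicates("patient_id", keep="first")
    y = df[label_col].to_numpy(dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes must be nonempty (nonfasting={n_pos}, fasting={n_neg})"
        )
    n_min = min(n_pos, n_neg)
    rng = np.random.default_rng(seed)
    parts = []
    for val in (True, False):
        cls = df[y == val]
        if len(cls) > n_min:
            cls = cls.iloc[np.sort(rng.choice(len(cls), n_min, replace=False))]
        parts.append(cls)
    out = pd.concat(parts).sort_index().reset_index(drop=True)
    return out


def split_train_test(
    balanced: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class train/test split, rounding the remainder toward train.

    The two outputs are disjoint, their union is the input, and the class
    ratio of a 1:1 input is preserved exactly in both.
    """
    label_col = spec.stratify_on
    y = balanced[label_col].to_numpy(dtype=bool)
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts = [], []
    for val in (True, False):
        cls = balanced[y == val]
        n = len(cls)
        if n < 5:
            raise ValueError(f"need at least 5 rows per class, got {n}")
        # guard the floor against float error in (1 - train_fraction)
        n_test = int(np.floor(round(n * (1.0 - spec.train_fraction), 9)))
        perm = rng.permutation(n)
        test_parts.append(cls.iloc[np.sort(perm[:n_test])])
        train_parts.append(cls.iloc[np.sort(perm[n_test:])])
    train = pd.concat(train_parts).sort_index().reset_index(drop=True)
    test = pd.concat(test_parts).sort_index().reset_index(drop=True)
    return train, test
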