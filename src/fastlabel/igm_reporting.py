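"""Ineffective glucose measurements (IGM) and period prevalence reports.

A fasting-qualified glucose at or above the 126 mg/dL diagnostic threshold
should, in a patient without known diabetes, trigger a diagnosis.  When it
never does — no DM code and no glucose-lowering medication at any point in
the observation window — the measurement changed nothing clinically: an
*ineffective glucose measurement*.  Comparing IGM prevalence between
ontological fasting (order-label based) and algorithm-verified fasting
quantifies how much apparent "undiagnosed diabetes" is actually nonfasting
noise.

Reports are organised in two-calendar-year periods with five counts:

  A  patients with any AC_ontological record in the period;
  B  patients with AC_ontological ≥ 126 mg/dL            (% of A, 1 dp);
  C  IGM patients among B                                 (% of B, 1 dp);
  D  patients with algorithm-verified AC ≥ 126 mg/dL      (% of A, 1 dp);
  E  IGM patients among D                                 (% of D, 2 dp).

Percentages round half away from zero at the stated precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "IGMPeriodSummary",
    "round_half_away",
    "flag_igm",
    "assign_periods",
    "summary_from_counts",
    "period_prevalence",
    "density_summaries",
]

DIAG_CUT_MGDL = 126.0


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention)."""
    if not np.isfinite(x):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(abs(float(x))).quantize(q, rounding=ROUND_HALF_UP)
                 * (1 if x >= 0 else -1))


@dataclass
class IGMPeriodSummary:
    """Counts A–E for one calendar period with their printed-style ratios."""

    period: str
    A: int
    B: int
    C: int
    D: int
    E: int

    def __post_init__(self) -> None:
        if not (self.C <= self.B <= self.A and self.E <= self.D <= self.A
                and self.D <= self.B or self.A == 0):
            # D <= B holds when verified fasting records are a subset of the
            # ontological records; external counts may legitimately break it.
            pass

    @property
    def pct_B_over_A(self) -> float:
        return round_half_away(100.0 * self.B / self.A, 1) if self.A else float("nan")

    @property
    def pct_C_over_B(self) -> float:
        return round_half_away(100.0 * self.C / self.B, 1) if self.B else float("nan")

    @property
    def pct_D_over_A(self) -> float:
        return round_half_away(100.0 * self.D / self.A, 1) if self.A else float("nan")

    @property
    def pct_E_over_D(self) -> float:
        return round_half_away(100.0 * self.E / self.D, 2) if self.D else float("nan")

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "A": self.A, "B": self.B, "C": self.C, "D": self.D, "E": self.E,
            "pct_B_over_A": self.pct_B_over_A,
            "pct_C_over_B": self.pct_C_over_B,
            "pct_D_over_A": self.pct_D_over_A,
            "pct_E_over_D": self.pct_E_over_D,
        }


def summary_from_counts(period: str, A: int, B: int, C: int, D: int, E: int
                        ) -> IGMPeriodSummary:
    """Build a period summary directly from counts (ratio arithmetic only)."""
    return IGMPeriodSummary(period=period, A=A, B=B, C=C, D=D, E=E)


def flag_igm(
    samples: pd.DataFrame,
    patients: pd.DataFrame,
    fasting_col: str,
    window_end,
    glucose_col: str = "value_mgdl",
    cut: float = DIAG_CUT_MGDL,
) -> pd.Series:
    """Per-sample IGM flag (nullable boolean).

    IGM iff the sample is fasting under ``fasting_col``, glucose ≥ ``cut``,
    and the patient is never diagnosed with DM (ICD code or glucose-lowering
    medication, whichever is earliest) on or before ``window_end``.
    Patients absent from the timeline table are unevaluable → missing flag.
    """
    window_end = pd.Timestamp(window_end)
    p = patients.set_index("patient_id")
    onset = pd.to_datetime(p["dm_onset_date"], errors="coerce")
    if "glucose_med_start" in p.columns:
        med = pd.to_datetime(p["glucose_med_start"], errors="coerce")
        onset = onset.combine(med, lambda a, b: min(
            [d for d in (a, b) if pd.notna(d)], default=pd.NaT))
    known = samples["patient_id"].isin(p.index).to_numpy()
    onset_s = onset.reindex(samples["patient_id"]).to_numpy()

    fasting = samples[fasting_col].to_numpy()
    fasting = np.asarray([bool(v) if pd.notna(v) else False for v in fasting])
    high = samples[glucose_col].to_numpy(dtype=float) >= cut
    never_dm = ~(pd.notna(onset_s) & (onset_s <= np.datetime64(window_end)))
    flags = pd.array(fasting & high & never_dm, dtype="boolean")
    flags[~known] = pd.NA
    return pd.Series(flags, index=samples.index, name="igm")


def assign_periods(dates, period_range: tuple[int, int]) -> pd.Series:
    """Two-calendar-year period labels, e.g. ``"2003-2004"``."""
    years = pd.to_datetime(pd.Series(dates)).dt.year
    first = period_range[0]
    start = first + 2 * ((years - first) // 2)
    return start.astype(str) + "-" + (start + 1).astype(str)


def _patient_level(df: pd.DataFrame, mask) -> int:
    return int(df.loc[np.asarray(mask, dtype=bool), "patient_id"].nunique())


def period_prevalence(
    samples: pd.DataFrame,
    patients: pd.DataFrame,
    period_range: tuple[int, int],
    verified_fasting_col: str = "algorithm_fasting",
    window_end=None,
    cut: float = DIAG_CUT_MGDL,
) -> pd.DataFrame:
    """Per-period IGM prevalence table (counts A–E and their ratios).

    ``samples`` must carry AC_ontological records with ``patient_id``,
    ``collection_datetime``, ``value_mgdl`` and a boolean
    ``verified_fasting_col`` (algorithm-verified fasting; missing values
    count as not verified).  Counts are patient-level: a patient enters B
    (or D) in a period if any qualifying record exists in that period.
    """
    if window_end is None:
        window_end = pd.Timestamp(f"{period_range[1]}-12-31")
    df = samples.copy()
    df["_period"] = assign_periods(df["collection_datetime"], period_range).to_numpy()
    df["_high"] = df["value_mgdl"].to_numpy(dtype=float) >= cut
    # unevaluable patients (missing timeline) are treated as non-IGM here;
    # flag_igm exposes the missing flags for separate accounting
    df["_ont_igm"] = (
        flag_igm(df.assign(_always=True), patients, "_always", window_end, cut=cut)
        .fillna(False)
        .to_numpy(dtype=bool)
    )
    ver = df[verified_fasting_col]
    df["_ver"] = np.asarray([bool(v) if pd.notna(v) else False for v in ver])
    df["_ver_igm"] = df["_ont_igm"] & df["_ver"]

    labels = sorted(
        f"{y}-{y + 1}" for y in range(period_range[0], period_range[1] + 1, 2)
    )
    rows = []
    for period in labels:
        g = df[df["_period"] == period]
        A = int(g["patient_id"].nunique())
        B = _patient_level(g, g["_high"])
        C = _patient_level(g, g["_high"] & g["_ont_igm"])
        D = _patient_level(g, g["_high"] & g["_ver"])
        E = _patient_level(g, g["_high"] & g["_ver"] & g["_ver_igm"])
        rows.append(summary_from_counts(period, A, B, C, D, E).to_dict())
    return pd.DataFrame(rows)


def density_summaries(
    labeled: pd.DataFrame,
    glucose_col: str = "glucose_mgdl",
    fasting_col: str = "theoretical_fasting",
    dm_col: str = "dm_status",
    min_n: int = 100,
    grid: tuple[float, float, int] = (40.0, 400.0, 721),
) -> pd.DataFrame:
    """Gaussian-KDE peak and landmark tail masses per stratum.

    Strata are fasting/nonfasting × DM/non-DM.  The peak is the mode of the
    kernel density on a fixed glucose grid; the masses below 100 and above
    126 mg/dL are empirical fractions.  Strata under ``min_n`` samples are
    flagged ``low_n``.
    """
    xs = np.linspace(*grid)
    rows = []
    df = labeled[labeled[fasting_col].notna()]
    for dm in (False, True):
        for fasting in (True, False):
            mask = (df[dm_col].to_numpy(dtype=bool) == dm) & (
                df[fasting_col].to_numpy(dtype=bool) == fasting
            )
            g = df.loc[mask, glucose_col].to_numpy(dtype=float)
            name = f"{'fasting' if fasting else 'nonfasting'}_{'dm' if dm else 'nondm'}"
            row = {
                "stratum": name,
                "n": int(g.size),
                "low_n": bool(g.size < min_n),
                "peak_mgdl": np.nan,
                "mass_below_100": np.nan,
                "mass_above_126": np.nan,
            }
            if g.size >= 2 and np.std(g) > 0:
                kde = gaussian_kde(g)
                row["peak_mgdl"] = float(xs[np.argmax(kde(xs))])
                row["mass_below_100"] = float(np.mean(g < 100.0))
                row["mass_above_126"] = float(np.mean(g > 126.0))
            elif g.size:
                row["peak_mgdl"] = float(g[0])
                row["mass_below_100"] = float(np.mean(g < 100.0))
                row["mass_above_126"] = float(np.mean(g > 126.0))
            rows.append(row)
    return pd.DataFrame(rows)
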