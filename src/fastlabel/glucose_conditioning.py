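"""Rule-based derivation of ontological fasting glucose (AC_ontological).

Raw laboratory glucose tables mix fasting orders with postprandial and
random draws, point-of-care values, corrupted entries and repeat draws.
This module reduces a raw table to the records that can plausibly be
*ontological* fasting measurements, and accounts for every input row in an
exclusion ledger (the dispositions partition the input exactly).

Rules, applied in order; the first matching rule supplies the reason code:

1. value validity — nonnumeric raw values, values > 1000 mg/dL and zero
   values are excluded (negative or non-finite parses count as nonnumeric);
2. missing collection timestamp — excluded as a data error;
3. care setting — only outpatient records are retained;
4. order label — post-cibum (PC) and random draws are excluded;
5. annotations — records tagged "one-touch", "bedside check", "PC" or other
   configured nonfasting tags are excluded (case-insensitive exact tags, not
   free-text mining);
6. same-day repeats — for one patient and calendar day, only the
   chronologically first surviving record is retained; later draws follow
   possible food intake.  Ties on timestamp break by record id.

"Higher than 1000 mg/dL" is strict (1000.0 is retained) and "zero" excludes
exactly 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_NONFASTING_TAGS",
    "REASONS",
    "filter_valid_values",
    "derive_ontological",
    "condition",
]

DEFAULT_NONFASTING_TAGS = frozenset(
    {"one_touch", "one-touch", "bedside_check", "bedside check", "pc", "pc_note",
     "food_intake_note"}
)

REASONS = (
    "nonnumeric",
    "gt_1000",
    "zero",
    "missing_timestamp",
    "non_outpatient",
    "label_pc_or_random",
    "annotation_nonfasting",
    "same_day_duplicate",
    "retained",
)


def _ledger(records: pd.DataFrame, reason: str, disposition: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": records["record_id"].to_numpy(),
            "disposition": disposition,
            "reason": reason,
        }
    )


def filter_valid_values(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records whose raw value is nonnumeric, zero or above 1000 mg/dL.

    Returns ``(retained, ledger_rows)``.  Retained records gain a float
    ``value_mgdl`` column with 0 < value ≤ 1000; every excluded record gets
    a ledger row with its reason.
    """
    df = records.copy()
    value = pd.to_numeric(df["raw_value"], errors="coerce")
    nonnumeric = value.isna() | ~np.isfinite(value.fillna(0.0)) | (value < 0)
    zero = ~nonnumeric & (value == 0)
    too_big = ~nonnumeric & (value > 1000)

    ledger = pd.concat(
        [
            _ledger(df[nonnumeric], "nonnumeric", "excluded"),
            _ledger(df[too_big], "gt_1000", "excluded"),
            _ledger(df[zero], "zero", "excluded"),
        ],
        ignore_index=True,
    )
    keep = ~(nonnumeric | zero | too_big)
    retained = df[keep].copy()
    retained["value_mgdl"] = value[keep].astype(float)
    return retained, ledger


def derive_ontological(
    records: pd.DataFrame,
    tag_vocab: frozenset[str] | set[str] = DEFAULT_NONFASTING_TAGS,
    require_outpatient: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce value-valid records to AC_ontological, with ledger rows.

    ``annotations`` may be a string of ``;``-separated tags or empty/NaN.
    """
    df = records.copy()
    vocab = {t.strip().lower() for t in tag_vocab}

    dt = pd.to_datetime(df["collection_datetime"], errors="coerce")
    missing_ts = dt.isna()

    setting = df["setting"].astype(str).str.lower()
    bad_setting = (
        ~missing_ts & (setting != "outpatient") if require_outpatient
        else pd.Series(False, index=df.index)
    )

    label = df["order_label"].astype(str).str.upper()
    bad_label = ~missing_ts & ~bad_setting & (label != "AC")

    def _tagged(ann) -> bool:
        if not isinstance(ann, str) or not ann.strip():
            return False
        return any(t.strip().lower() in vocab for t in ann.split(";"))

    tagged = df["annotations"].map(_tagged).astype(bool)
    bad_annot = ~missing_ts & ~bad_setting & ~bad_label & tagged

    survivors = ~(missing_ts | bad_setting | bad_label | bad_annot)
    surv = df[survivors].copy()
    surv["_dt"] = dt[survivors]
    surv["_day"] = surv["_dt"].dt.normalize()
    order = surv.sort_values(["patient_id", "_day", "_dt", "record_id"],
                             kind="mergesort")
    first = ~order.duplicated(["patient_id", "_day"], keep="first")
    dup_ids = order.loc[~first, "record_id"]
    retained = order[first].drop(columns=["_dt", "_day"])
    # restore input row order for the retained set
    retained = retained.sort_index()

    ledger = pd.concat(
        [
            _ledger(df[missing_ts], "missing_timestamp", "excluded"),
            _ledger(df[bad_setting], "non_outpatient", "excluded"),
            _ledger(df[bad_label], "label_pc_or_random", "excluded"),
            _ledger(df[bad_annot], "annotation_nonfasting", "excluded"),
            _ledger(df[df["record_id"].isin(dup_ids)], "same_day_duplicate",
                    "excluded"),
            _ledger(retained, "retained", "ontological_AC"),
        ],
        ignore_index=True,
    )
    return retained.reset_index(drop=True), ledger


def condition(
    records: pd.DataFrame,
    tag_vocab: frozenset[str] | set[str] = DEFAULT_NONFASTING_TAGS,
    require_outpatient: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full conditioning chain: value filter then ontological derivation.

    Returns ``(ac_ontological, ledger)``.  The ledger has exactly one row
    per input record (conservation) and the operation is idempotent: a
    second pass retains everything it is given.
    """
    valid, ledger_values = filter_valid_values(records)
    retained, ledger_rules = derive_ontological(
        valid, tag_vocab=tag_vocab, require_outpatient=require_outpatient
    )
    ledger = pd.concat([ledger_values, ledger_rules], ignore_index=True)
    if len(ledger) != len(records):
        raise AssertionError(
            "ledger conservation violated: "
            f"{len(ledger)} ledger rows for {len(records)} records"
        )
    return retained, ledger
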