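"""Pre/post clinical deltas and responder labels.

Response to therapy is judged by the change in three serum markers: PSA,
alkaline phosphatase (AP) and bone-specific alkaline phosphatase (bAP),
each computed as post-therapy minus pre-therapy. A strictly negative delta
(marker decreased) labels the patient a responder for that marker; a delta
of exactly 0 counts as non-response. ECOG performance status is carried
through as ``ecog_change`` but has no responder rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["MARKERS", "compute_deltas", "summarize_response"]

MARKERS = ("psa", "ap", "bap")

_REQUIRED = [
    "patient_id",
    "pre_psa", "post_psa",
    "pre_ap", "post_ap",
    "pre_bap", "post_bap",
    "ecog_pre", "ecog_post",
]


def compute_deltas(clinical: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: marker deltas, ECOG change and responder flags.

    Accepts the per-lesion clinical table (clinical values repeated across a
    patient's lesion rows) or an already per-patient table; duplicates are
    collapsed after checking they agree. Missing or non-numeric cells raise
    with the offending patient id.
    """
    missing = [c for c in _REQUIRED if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table is missing columns: {missing}")
    per_patient = clinical[_REQUIRED].drop_duplicates()
    dup = per_patient["patient_id"].duplicated()
    if dup.any():
        bad = sorted(per_patient.loc[dup, "patient_id"].unique())
        raise ValueError(f"inconsistent clinical values for patient(s): {bad}")
    per_patient = per_patient.set_index("patient_id")

    numeric = per_patient.apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1)
    if bad_rows.any():
        bad = sorted(numeric.index[bad_rows])
        raise ValueError(f"missing or non-numeric clinical values for patient(s): {bad}")
    for marker in MARKERS:
        nonpos = numeric[f"pre_{marker}"] <= 0
        if nonpos.any():
            bad = sorted(numeric.index[nonpos])
            raise ValueError(f"non-positive pre_{marker} for patient(s): {bad}")

    out = pd.DataFrame(index=numeric.index)
    for marker in MARKERS:
        delta = numeric[f"post_{marker}"] - numeric[f"pre_{marker}"]
        out[f"delta_{marker}"] = delta
        out[f"responder_{marker}"] = delta < 0  # strict decrease
    out["ecog_change"] = (numeric["ecog_post"] - numeric["ecog_pre"]).astype(int)
    return out.reset_index()


def _pct(count: int, n: int, ndigits: int) -> float:
    return round(100.0 * count / n, ndigits)


def summarize_response(deltas: pd.DataFrame, ndigits: int = 2) -> dict:
    """Responder counts/percentages per marker and for joint decreases.

    Percentages use plain rounding at ``ndigits`` decimals; the raw fraction
    is always included so no information is lost to formatting.
    """
    n = len(deltas)
    if n == 0:
        raise ValueError("empty delta table")
    out: dict[str, dict] = {"n_patients": n}
    for marker in MARKERS:
        count = int(deltas[f"responder_{marker}"].sum())
        out[marker] = {
            "responders": count,
            "percent": _pct(count, n, ndigits),
            "fraction": count / n,
        }
    joint_pa = int((deltas["responder_psa"] & deltas["responder_ap"]).sum())
    joint_pab = int(
        (deltas["responder_psa"] & deltas["responder_ap"] & deltas["responder_bap"]).sum()
    )
    out["psa_and_ap"] = {
        "responders": joint_pa, "percent": _pct(joint_pa, n, ndigits), "fraction": joint_pa / n,
    }
    out["psa_and_ap_and_bap"] = {
        "responders": joint_pab, "percent": _pct(joint_pab, n, ndigits), "fraction": joint_pab / n,
    }
    out["ecog_changed"] = int((deltas["ecog_change"] != 0).sum())
    return out
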