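"""Per-patient, per-criteria applicability screening.

Two filters gate classification.  *Measurability*: the target metric must
be measurable at baseline — for the SUL/SUVpeak-based rule sets at least
one lesion's peak value must reach 1.5 x (liver mean + 2 SD) of the 3-cm
liver reference sphere; the SUVmax-based rule sets only need a lesion with
positive SUVmax.  *Comparability*: the baseline and follow-up liver
reference means may differ by at most 20 % — a drift beyond that flags the
scan pair as not comparable for the PERCIST family (EORTC is exempt and
classifies every patient).  Non-comparability dominates non-availability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from petresponse.criteria import CRITERIA, PERCIST_FAMILY
from petresponse.types import ApplicabilityStatus, Status

#: liver-drift metric checked per criteria (None = no comparability filter).
DEFAULT_COMPARABILITY_METRIC: dict[str, str | None] = {
    "percist10": "sulmean",
    "mpercist": "sulmean",
    "percistmax": "suvmean",
    "eortc": None,
}

MEASURABILITY_MULTIPLIER = 1.5
COMPARABILITY_LIMIT_PCT = 20.0


def measurable(lesion_sulpeak: float, liver, multiplier: float = MEASURABILITY_MULTIPLIER) -> bool:
    """Is a lesion's SULpeak at least ``multiplier`` x (liver SULmean + 2 SD)?

    ``liver`` is a :class:`~petresponse.types.LiverReference` (or anything
    with ``sulmean``/``sul_sd``).  The boundary is inclusive ("at least").
    """
    if lesion_sulpeak is None or not np.isfinite(lesion_sulpeak):
        return False
    floor = multiplier * (liver.sulmean + 2.0 * liver.sul_sd)
    return lesion_sulpeak >= floor


def comparable(
    liver_baseline_mean: float,
    liver_followup_mean: float,
    limit_pct: float = COMPARABILITY_LIMIT_PCT,
) -> bool:
    """Is the liver-reference drift within the tolerated percent difference?

    Drift is 100 * |follow - base| / base; exactly ``limit_pct`` is still
    comparable (only *exceeding* the limit triggers exclusion).
    """
    if not liver_baseline_mean > 0:
        raise ValueError("baseline liver mean must be > 0")
    drift = 100.0 * abs(liver_followup_mean - liver_baseline_mean) / liver_baseline_mean
    return drift <= limit_pct


def _liver_floor(liver_row: pd.Series, metric: str, multiplier: float) -> float:
    if metric == "sulpeak":
        return multiplier * (liver_row["liver_sulmean"] + 2.0 * liver_row["liver_sul_sd"])
    return multiplier * (liver_row["liver_suvmean"] + 2.0 * liver_row["liver_suv_sd"])


def assess_patient(
    lesions_baseline: pd.DataFrame,
    lesions_followup: pd.DataFrame,
    liver_baseline: pd.Series,
    liver_followup: pd.Series,
    criteria_name: str,
    multiplier: float = MEASURABILITY_MULTIPLIER,
    limit_pct: float = COMPARABILITY_LIMIT_PCT,
    comparability_metric: str | None = "default",
) -> ApplicabilityStatus:
    """Applicability of one criteria set for one patient's scan pair.

    ``lesions_baseline``/``lesions_followup`` are that patient's lesion
    rows; ``liver_baseline``/``liver_followup`` the per-scan liver
    reference rows (``liver_sulmean``, ``liver_sul_sd``, ``liver_suvmean``,
    ``liver_suv_sd``).  ``comparability_metric`` overrides which liver mean
    the 20 % rule reads ("sulmean"/"suvmean"/None); "default" uses the
    per-criteria mapping.
    """
    if criteria_name not in CRITERIA:
        raise ValueError(f"unknown criteria {criteria_name!r}")
    if lesions_baseline.empty or lesions_followup.empty:
        raise ValueError("both baseline and follow-up lesion rows are required")

    if comparability_metric == "default":
        comparability_metric = DEFAULT_COMPARABILITY_METRIC[criteria_name]

    if comparability_metric is not None and criteria_name in PERCIST_FAMILY:
        column = f"liver_{comparability_metric}"
        base, follow = float(liver_baseline[column]), float(liver_followup[column])
        if not comparable(base, follow, limit_pct):
            drift = 100.0 * abs(follow - base) / base
            return ApplicabilityStatus(
                Status.NOT_COMPARABLE,
                f"liver {comparability_metric} drift {drift:.1f}% exceeds {limit_pct:g}%",
            )

    index = lesions_baseline[~lesions_baseline.get("is_new", False).astype(bool)]
    metric = CRITERIA[criteria_name].metric
    if metric in ("sulpeak", "suvpeak"):
        floor = _liver_floor(liver_baseline, metric, multiplier)
        values = pd.to_numeric(index[metric], errors="coerce")
        if not (values >= floor).any():
            return ApplicabilityStatus(
                Status.NOT_AVAILABLE,
                f"no baseline lesion with {metric} >= {multiplier:g} x "
                f"(liver mean + 2 SD) = {floor:.2f}",
            )
    else:  # suvmax-based rule sets only need an avid lesion
        values = pd.to_numeric(index["suvmax"], errors="coerce")
        if not (values > 0).any():
            return ApplicabilityStatus(
                Status.NOT_AVAILABLE, "no baseline lesion with positive SUVmax"
            )
    return ApplicabilityStatus(Status.OK)


def assess_cohort(
    lesions: pd.DataFrame,
    liver: pd.DataFrame,
    criteria: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Applicability table: one row per patient x criteria (mirrors n.a./n.c. annotations)."""
    criteria = list(CRITERIA) if criteria is None else list(criteria)
    liver_idx = liver.set_index(["patient_id", "scan"])
    rows = []
    for patient_id, group in lesions.groupby("patient_id", sort=True):
        base = group[group["scan"] == "baseline"]
        follow = group[group["scan"] == "followup"]
        for name in criteria:
            status = assess_patient(
                base,
                follow,
                liver_idx.loc[(patient_id, "baseline")],
                liver_idx.loc[(patient_id, "followup")],
                name,
                **kwargs,
            )
            rows.append(
                {
                    "patient_id": patient_id,
                    "criteria": name,
                    "status": status.status.value,
                    "reason": status.reason,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "criteria", "status", "reason"])
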