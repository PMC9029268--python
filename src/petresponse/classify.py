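"""Cohort-level response classification under hottest-lesion / all-lesions targets.

Target selection follows the conventions of the two criteria families:

* PERCIST family, hottest mode: the target is the single hottest lesion of
  *each scan independently* — baseline and follow-up targets may differ.
* EORTC, hottest mode: the baseline-hottest lesion is tracked and its own
  follow-up value used.
* all-lesions mode (both families): the index lesions are the per-
  compartment baseline-hottest lesions and the percent change is computed
  on the *sum* of the metric over them (same lesions at both scans).

Ties for "hottest" break by larger MTV, then lexicographic lesion ID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from petresponse.criteria import (
    CRITERIA,
    CriteriaSpec,
    _classify,
    dichotomize,
    percent_change,
    resolve_criteria,
)
from petresponse.eligibility import assess_patient
from petresponse.types import ApplicabilityStatus, ResponseResult, Status

SELECTIONS = ("hottest", "all")


@dataclass(frozen=True)
class TargetSelection:
    """Target metric values per scan plus the lesion IDs behind them."""

    baseline_value: float
    followup_value: float
    baseline_ids: tuple[str, ...]
    followup_ids: tuple[str, ...]


def _rank(frame: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Deterministic hotness ordering: metric desc, MTV desc, lesion_id asc."""
    return frame.sort_values(
        [metric, "mtv_cm3", "lesion_id"], ascending=[False, False, True]
    )


def _index_lesions(baseline: pd.DataFrame, metric: str) -> pd.DataFrame:
    """One index lesion per compartment: the baseline-hottest of each."""
    return (
        _rank(baseline, metric).groupby("compartment", sort=True).head(1)
    )


def select_target(
    lesions_baseline: pd.DataFrame,
    lesions_followup: pd.DataFrame,
    metric: str,
    mode: str = "hottest",
    criteria: str = "percist10",
) -> TargetSelection:
    """Pick the target value(s) to compare between scans.

    ``lesions_baseline``/``lesions_followup`` are one patient's lesion rows
    (new lesions are ignored here; they enter through the new-lesion rule).
    """
    if mode not in SELECTIONS:
        raise ValueError(f"mode must be one of {SELECTIONS}, got {mode!r}")
    base = lesions_baseline[~lesions_baseline.get("is_new", False).astype(bool)]
    follow = lesions_followup[~lesions_followup.get("is_new", False).astype(bool)]
    if base.empty:
        raise ValueError("no baseline lesion to select a target from")

    if mode == "hottest":
        hottest_base = _rank(base, metric).iloc[0]
        if criteria == "eortc":
            # track the baseline-hottest lesion's own follow-up value
            match = follow[follow["lesion_id"] == hottest_base["lesion_id"]]
            if match.empty:
                raise ValueError(
                    f"baseline-hottest lesion {hottest_base['lesion_id']!r} "
                    "has no follow-up row"
                )
            row = match.iloc[0]
            return TargetSelection(
                float(hottest_base[metric]),
                float(row[metric]),
                (str(hottest_base["lesion_id"]),),
                (str(row["lesion_id"]),),
            )
        if follow.empty:
            raise ValueError("no follow-up lesion to select a target from")
        hottest_follow = _rank(follow, metric).iloc[0]
        return TargetSelection(
            float(hottest_base[metric]),
            float(hottest_follow[metric]),
            (str(hottest_base["lesion_id"]),),
            (str(hottest_follow["lesion_id"]),),
        )

    index = _index_lesions(base, metric)
    ids = tuple(sorted(index["lesion_id"].astype(str)))
    follow_rows = follow[follow["lesion_id"].isin(index["lesion_id"])]
    if set(follow_rows["lesion_id"]) != set(index["lesion_id"]):
        missing = set(index["lesion_id"]) - set(follow_rows["lesion_id"])
        raise ValueError(f"index lesions missing at follow-up: {sorted(missing)}")
    return TargetSelection(
        float(index[metric].sum()), float(follow_rows[metric].sum()), ids, ids
    )


def _size_change_pct(
    base: pd.DataFrame, follow: pd.DataFrame, spec: CriteriaSpec, mode: str, metric: str
) -> float | None:
    """Size-progression input: target MTV change (PERCIST) or longest-diameter change (EORTC)."""
    column = "longest_diameter_mm" if spec.name == "eortc" else "mtv_cm3"
    follow_by_id = follow.set_index("lesion_id")[column]
    if mode == "hottest":
        target_id = _rank(base, metric).iloc[0]["lesion_id"]
        base_val = float(base.set_index("lesion_id").loc[target_id, column])
        if target_id not in follow_by_id.index or not base_val > 0:
            return None
        return percent_change(base_val, float(follow_by_id[target_id]))
    index = _index_lesions(base, metric)
    if spec.name == "eortc":
        # worst (largest) diameter change across index lesions
        changes = [
            percent_change(float(row[column]), float(follow_by_id[row["lesion_id"]]))
            for _, row in index.iterrows()
            if row["lesion_id"] in follow_by_id.index and row[column] > 0
        ]
        return max(changes) if changes else None
    base_sum = float(index[column].sum())
    follow_sum = float(follow_by_id.reindex(index["lesion_id"]).fillna(0.0).sum())
    return percent_change(base_sum, follow_sum) if base_sum > 0 else None


def _background_level(liver_followup: pd.Series, spec: CriteriaSpec) -> float:
    if spec.name == "percist10":
        return float(liver_followup["liver_sulmean"])
    if spec.name == "eortc":
        return float(
            liver_followup["liver_suvmean"] + 2.0 * liver_followup["liver_suv_sd"]
        )
    return float(liver_followup["liver_suvmean"])


def classify_patient(
    lesions_baseline: pd.DataFrame,
    lesions_followup: pd.DataFrame,
    liver_baseline: pd.Series,
    liver_followup: pd.Series,
    spec: CriteriaSpec,
    mode: str = "hottest",
    patient_id: str = "",
    applicability: ApplicabilityStatus | None = None,
) -> ResponseResult:
    """Classify one patient under one rule set and target-selection mode."""
    if applicability is None:
        applicability = assess_patient(
            lesions_baseline, lesions_followup, liver_baseline, liver_followup, spec.name
        )
    if not applicability.ok:
        return ResponseResult(
            patient_id=str(patient_id),
            criteria=spec.name,
            selection=mode,
            applicability=applicability,
        )

    base = lesions_baseline[~lesions_baseline.get("is_new", False).astype(bool)]
    follow_all = lesions_followup
    follow = follow_all[~follow_all.get("is_new", False).astype(bool)]
    new_lesion = bool(follow_all.get("is_new", False).astype(bool).any())

    target = select_target(base, follow, spec.metric, mode, spec.name)
    change = percent_change(target.baseline_value, target.followup_value)
    category = _classify(
        spec,
        target.baseline_value,
        target.followup_value,
        new_lesion=new_lesion,
        size_change_pct=_size_change_pct(base, follow, spec, mode, spec.metric),
        background_level=_background_level(liver_followup, spec),
        followup_lesion_values=tuple(follow[spec.metric].astype(float)),
        all_resolved=bool(follow["resolved"].astype(bool).all())
        if "resolved" in follow
        else None,
    )
    return ResponseResult(
        patient_id=str(patient_id),
        criteria=spec.name,
        selection=mode,
        applicability=applicability,
        category=category,
        dichotomy=dichotomize(category),
        percent_change=change,
        target_baseline_ids=target.baseline_ids,
        target_followup_ids=target.followup_ids,
        new_lesion=new_lesion,
    )


def classify_cohort(
    lesions: pd.DataFrame,
    liver: pd.DataFrame,
    criteria: list[str] | None = None,
    selections: tuple[str, ...] = SELECTIONS,
) -> pd.DataFrame:
    """Classify every patient under every requested rule set and selection mode.

    Returns one row per patient x criteria x selection with columns
    ``patient_id, criteria, selection, status, reason, category, dichotomy,
    percent_change, new_lesion``; n.a./n.c. patients keep empty category.
    Raises on duplicate (patient, scan, lesion) rows.
    """
    duplicates = lesions.duplicated(subset=["patient_id", "scan", "lesion_id"])
    if duplicates.any():
        bad = lesions.loc[duplicates, ["patient_id", "scan", "lesion_id"]]
        raise ValueError(f"duplicate patient/scan/lesion rows:\n{bad}")
    specs = resolve_criteria(criteria)
    liver_idx = liver.set_index(["patient_id", "scan"])
    rows = []
    for patient_id, group in lesions.groupby("patient_id", sort=True):
        base = group[group["scan"] == "baseline"]
        follow = group[group["scan"] == "followup"]
        if base.empty or follow.empty:
            raise ValueError(f"patient {patient_id!r} lacks a baseline or follow-up scan")
        liver_b = liver_idx.loc[(patient_id, "baseline")]
        liver_f = liver_idx.loc[(patient_id, "followup")]
        for spec in specs:
            status = assess_patient(base, follow, liver_b, liver_f, spec.name)
            for mode in selections:
                result = classify_patient(
                    base, follow, liver_b, liver_f, spec, mode,
                    patient_id=patient_id, applicability=status,
                )
                rows.append(
                    {
                        "patient_id": result.patient_id,
                        "criteria": result.criteria,
                        "selection": result.selection,
                        "status": result.applicability.status.value,
                        "reason": result.applicability.reason,
                        "category": result.category.value if result.category else "",
                        "dichotomy": result.dichotomy.value if result.dichotomy else "",
                        "percent_change": result.percent_change
                        if result.percent_change is not None
                        else np.nan,
                        "new_lesion": result.new_lesion,
                    }
                )
    return pd.DataFrame(rows)


def category_counts(results: pd.DataFrame) -> dict:
    """Per criteria x selection summary: category counts plus n.a./n.c. tallies."""
    summary: dict = {}
    for (name, mode), group in results.groupby(["criteria", "selection"], sort=True):
        classified = group[group["status"] == Status.OK.value]
        counts = classified["category"].value_counts().to_dict()
        summary[f"{name}/{mode}"] = {
            "n_classified": int(len(classified)),
            "CMR": int(counts.get("CMR", 0)),
            "PMR": int(counts.get("PMR", 0)),
            "SMD": int(counts.get("SMD", 0)),
            "PMD": int(counts.get("PMD", 0)),
            "DC": int((classified["dichotomy"] == "DC").sum()),
            "PD": int((classified["dichotomy"] == "PD").sum()),
            "not_available": int((group["status"] == Status.NOT_AVAILABLE.value).sum()),
            "not_comparable": int((group["status"] == Status.NOT_COMPARABLE.value).sum()),
        }
    return summary
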