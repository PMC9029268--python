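"""End-to-end orchestration: generate -> screen -> classify -> compare.

A run is fully specified by a :class:`RunConfig`; identical config + seed
produces byte-identical artifacts.  Artifacts written to the output
directory: the cohort tables, the applicability table (n.a./n.c.
annotations), the classification table and category-count summary, a
group-wise percent-change summary with bootstrap-t p-values, the survival
table with KM curves and permutation log-rank report, and a manifest
recording the config hash, seed, thresholds and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from petresponse import io as prio
from petresponse.classify import SELECTIONS, _rank, category_counts, classify_cohort
from petresponse.criteria import CRITERIA, percent_change, resolve_criteria
from petresponse.eligibility import assess_cohort
from petresponse.simulate import (
    LESION_COLUMNS,
    CohortConfig,
    generate_lesion_table_cohort,
    generate_survival,
)
from petresponse.survival import compare_survival, km_curves, summarize_changes

REQUIRED_LESION_COLUMNS = [
    "patient_id", "scan", "lesion_id", "compartment", "suvmax", "suvmean",
    "suvpeak", "sulpeak", "mtv_cm3", "longest_diameter_mm", "is_new",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"                  # "synthetic" or "table"
    criteria: tuple[str, ...] | None = None  # None = all four rule sets
    selections: tuple[str, ...] = SELECTIONS
    sul_method: str = "lbm_janmahasatian"
    seed: int = 0
    out_dir: str = "petresponse_run"
    cohort: dict = field(default_factory=dict)   # CohortConfig overrides
    lesions_csv: str | None = None               # table mode inputs
    liver_csv: str | None = None
    survival_csv: str | None = None
    hazard_dc: float = float(np.log(2) / 35.6)   # per month; median 35.6 mo
    hazard_pd: float = float(np.log(2) / 24.9)   # per month; median 24.9 mo
    censor_rate: float = 0.3
    n_perm: int = 5000
    n_boot: int = 5000

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "table"):
            raise ValueError("mode must be 'synthetic' or 'table'")
        if self.criteria is not None and len(self.criteria) == 0:
            raise ValueError("at least one criteria set must be selected")
        resolve_criteria(self.criteria)
        for mode in self.selections:
            if mode not in SELECTIONS:
                raise ValueError(f"unknown selection mode {mode!r}")


def validate_table(table: pd.DataFrame | str | Path) -> list[dict]:
    """Schema diagnostics for a lesion table; empty list means well-formed.

    Reports missing columns, non-positive uptake values, duplicate
    (patient, scan, lesion) rows, and orphan scans (a patient with only
    one of baseline/follow-up).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    diagnostics: list[dict] = []
    missing = [c for c in REQUIRED_LESION_COLUMNS if c not in table.columns]
    for column in missing:
        diagnostics.append({"kind": "missing_column", "detail": column})
    if missing:
        return diagnostics
    for column in ("suvmax", "suvmean"):
        bad = table.index[pd.to_numeric(table[column], errors="coerce") <= 0]
        for row in bad:
            diagnostics.append(
                {"kind": "non_positive_uptake",
                 "detail": f"row {row}: {column} <= 0"}
            )
    dup = table.duplicated(subset=["patient_id", "scan", "lesion_id"])
    for row in table.index[dup]:
        diagnostics.append({"kind": "duplicate_lesion", "detail": f"row {row}"})
    scans = table.groupby("patient_id")["scan"].agg(set)
    for pid, present in scans.items():
        for needed in ("baseline", "followup"):
            if needed not in present:
                diagnostics.append(
                    {"kind": "orphan_scan",
                     "detail": f"patient {pid}: missing {needed} scan"}
                )
    return diagnostics


def collect_metric_changes(lesions: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Per-patient percent changes for the group-wise change summary.

    For each rule set, classified (hottest-lesion) patients contribute the
    percent change on the rule set's own metric, grouped by its dichotomy;
    MTV and TLG changes track the baseline SUVmax-hottest lesion and are
    grouped by the EORTC dichotomy.
    """
    rows = []
    hottest = results[(results["selection"] == "hottest") & (results["status"] == "ok")]
    for _, rec in hottest.iterrows():
        metric = CRITERIA[rec["criteria"]].metric
        rows.append({
            "patient_id": rec["patient_id"],
            "group": rec["dichotomy"],
            "metric": f"{metric}_{rec['criteria']}",
            "pct_change": float(rec["percent_change"]),
        })
    eortc = hottest[hottest["criteria"] == "eortc"].set_index("patient_id")
    for pid, group in lesions.groupby("patient_id", sort=True):
        if pid not in eortc.index:
            continue
        base = group[(group["scan"] == "baseline") & (~group["is_new"].astype(bool))]
        follow = group[group["scan"] == "followup"].set_index("lesion_id")
        target = _rank(base, "suvmax").iloc[0]
        if target["lesion_id"] not in follow.index:
            continue
        follow_row = follow.loc[target["lesion_id"]]
        for metric in ("mtv_cm3", "tlg"):
            if float(target[metric]) > 0:
                rows.append({
                    "patient_id": pid,
                    "group": eortc.loc[pid, "dichotomy"],
                    "metric": f"{metric}_eortc",
                    "pct_change": percent_change(
                        float(target[metric]), float(follow_row[metric])
                    ),
                })
    return pd.DataFrame(rows, columns=["patient_id", "group", "metric", "pct_change"])


def _config_dict(config: RunConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["criteria"] = list(config.criteria) if config.criteria else sorted(CRITERIA)
    payload["selections"] = list(config.selections)
    payload["thresholds"] = {
        name: dataclasses.asdict(spec) for name, spec in CRITERIA.items()
        if name in payload["criteria"]
    }
    return payload


def run(config: RunConfig) -> dict:
    """Execute the pipeline and write all artifacts; returns the run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_csv(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        prio.write_csv(frame, path)
        written.append(path)

    def emit_json(payload: dict, name: str) -> None:
        path = out_dir / name
        prio.write_json(payload, path)
        written.append(path)

    try:
        if config.mode == "synthetic":
            cohort_config = CohortConfig(**{**config.cohort, "seed": config.seed})
            lesions, patients, liver = generate_lesion_table_cohort(cohort_config)
            emit_csv(patients, "patients.csv")
        else:
            if not (config.lesions_csv and config.liver_csv):
                raise ValueError("table mode requires lesions_csv and liver_csv")
            lesions = pd.read_csv(config.lesions_csv)
            liver = pd.read_csv(config.liver_csv)
            patients = None
        problems = validate_table(lesions[
            [c for c in LESION_COLUMNS if c in lesions.columns]
        ])
        if problems:
            raise ValueError(f"lesion table failed validation: {problems}")
        emit_csv(lesions, "lesions.csv")
        emit_csv(liver, "liver.csv")

        criteria = list(config.criteria) if config.criteria else sorted(CRITERIA)
        applicability = assess_cohort(lesions, liver, criteria)
        emit_csv(applicability, "applicability.csv")

        results = classify_cohort(lesions, liver, criteria, config.selections)
        emit_csv(results, "classification.csv")
        summary = category_counts(results)
        emit_json(summary, "classification_summary.json")

        changes = collect_metric_changes(lesions, results)
        change_summary, change_p = summarize_changes(
            changes, n_boot=config.n_boot, seed=config.seed
        )
        emit_csv(change_summary, "changes_summary.csv")

        # survival: synthetic mode simulates times from the hidden truth groups
        survival_report: dict = {}
        if config.mode == "synthetic" and patients is not None and len(patients):
            truth_groups = patients.rename(columns={"truth_dichotomy": "group"})[
                ["patient_id", "group"]
            ]
            survival = generate_survival(
                truth_groups, config.hazard_dc, config.hazard_pd,
                config.censor_rate, seed=config.seed + 1,
            )
        elif config.survival_csv:
            survival = pd.read_csv(config.survival_csv)
        else:
            survival = pd.DataFrame(
                columns=["patient_id", "time_months", "event", "group", "endpoint"]
            )
        if len(survival):
            emit_csv(survival, "survival.csv")
            hottest = results[
                (results["selection"] == "hottest") & (results["status"] == "ok")
            ]
            for name in criteria:
                sub = hottest[hottest["criteria"] == name][["patient_id", "dichotomy"]]
                joined = survival.drop(columns=["group"]).merge(
                    sub.rename(columns={"dichotomy": "group"}), on="patient_id"
                )
                if len(joined):
                    survival_report[name] = compare_survival(
                        joined, n_perm=config.n_perm, seed=config.seed
                    )
                    curves = km_curves(joined)
                    curves.insert(0, "criteria", name)
                    emit_csv(curves, f"km_{name}.csv")
            emit_json(survival_report, "survival_report.json")

        config_payload = _config_dict(config)
        config_json = json.dumps(config_payload, sort_keys=True)
        report = {
            "config": config_payload,
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "seed": config.seed,
            "version": "0.1.0",
            "classification_summary": summary,
            "change_pvalues": change_p,
            "survival": survival_report,
            "artifacts": sorted(p.name for p in written) + ["manifest.json"],
        }
        emit_json(report, "manifest.json")
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
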