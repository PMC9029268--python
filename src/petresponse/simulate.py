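"""Synthetic cohorts: voxel phantoms, lesion-level tables and linked survival.

The table generator emulates a two-scan (baseline / ~4-month follow-up)
metastatic thyroid-cancer cohort under tyrosine-kinase-inhibitor therapy:
a mix of complete responders, partial responders (uptake decline around
-46 +/- 25 %), stable patients and progressors (increase around
+92 +/- 34 %), occasional patients whose lesions sit below the liver
measurability floor, and scan pairs whose liver reference drifts beyond
the 20 % comparability limit.  Per-patient response profiles are drawn
from *untruncated* normals (clipped only at the physical -99 % bound, and
to +/-24 % for the stable profile so it stays inside every criterion's
stability band), so empirical group means converge to the configured
ones.  The assigned profile is recorded as hidden truth in the patient
attributes table, which the analysis stages never read.

Survival times are exponential with group-specific hazards; independent
exponential censoring is calibrated so the expected censored fraction
equals ``censor_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from petresponse.quantify import lean_body_mass_kg
from petresponse.types import PatientAttributes, Unit, VoxelVolume

COMPARTMENTS = ("thyroid_bed", "lymph_node", "visceral", "muscular", "osseous")
PROFILES = ("complete", "responder", "stable", "progressor")

LESION_COLUMNS = [
    "patient_id", "scan", "lesion_id", "compartment", "suvmax", "suvmean",
    "suvpeak", "sulpeak", "mtv_cm3", "tlg", "longest_diameter_mm", "is_new",
    "resolved",
]
LIVER_COLUMNS = [
    "patient_id", "scan", "liver_sulmean", "liver_sul_sd", "liver_suvmean",
    "liver_suv_sd",
]
PATIENT_COLUMNS = [
    "patient_id", "sex", "weight_kg", "height_cm", "injected_mbq",
    "truth_class", "truth_dichotomy", "truth_change_pct",
    "truth_mtv_change_pct", "flag_nonmeasurable", "flag_liver_drift",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the table-level cohort generator.

    Profile fractions default to the composition of a 25-patient
    RAI-refractory cohort (2 complete, 11 partial responders, 4 stable,
    8 progressors); uptake effect sizes default to the disease-control /
    progression group means of such a cohort (-46 +/- 25 % and
    +92 +/- 34 % on SUVpeak; MTV -52 +/- 31 % and +38 +/- 94 %).
    """

    n_patients: int = 25
    fraction_complete: float = 0.08
    fraction_responder: float = 0.44
    fraction_stable: float = 0.16
    fraction_progressor: float = 0.32
    responder_change_mean_sd: tuple[float, float] = (-46.0, 25.0)
    progressor_change_mean_sd: tuple[float, float] = (92.0, 34.0)
    stable_change_mean_sd: tuple[float, float] = (0.0, 8.0)
    responder_mtv_change_mean_sd: tuple[float, float] = (-52.0, 31.0)
    progressor_mtv_change_mean_sd: tuple[float, float] = (38.0, 94.0)
    p_new_lesion_in_progressor: float = 0.5
    p_nonmeasurable_patient: float = 0.08
    p_liver_drift_patient: float = 0.12
    lesions_per_patient_range: tuple[int, int] = (1, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = (
            self.fraction_complete, self.fraction_responder,
            self.fraction_stable, self.fraction_progressor,
        )
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"profile fractions must sum to 1, got {sum(fractions)}")
        if any(f < 0 for f in fractions):
            raise ValueError("profile fractions must be >= 0")
        for name in ("p_new_lesion_in_progressor", "p_nonmeasurable_patient",
                     "p_liver_drift_patient"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.lesions_per_patient_range
        if not (1 <= lo <= hi <= len(COMPARTMENTS)):
            raise ValueError(
                f"lesions_per_patient_range must satisfy 1 <= lo <= hi <= "
                f"{len(COMPARTMENTS)}, got {self.lesions_per_patient_range}"
            )
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")


def _allocate_counts(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder allocation so class counts are exact and deterministic."""
    raw = [f * n for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _equivalent_diameter_mm(mtv_cm3: float) -> float:
    return 2.0 * (3.0 * mtv_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def generate_lesion_table_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a longitudinal lesion table, patient attributes and liver stats.

    Returns ``(lesions, patients, liver)`` DataFrames.  Every patient has
    baseline and follow-up rows for each index lesion; new lesions appear
    as follow-up-only rows with ``is_new=True``.  The ``truth_*`` columns
    of the patients table are the injected ground truth and are never read
    by the analysis stages.
    """
    rng = np.random.default_rng(config.seed)
    fractions = [
        config.fraction_complete, config.fraction_responder,
        config.fraction_stable, config.fraction_progressor,
    ]
    counts = _allocate_counts(config.n_patients, fractions)
    profiles = np.repeat(PROFILES, counts)
    profiles = profiles[rng.permutation(config.n_patients)]

    lesion_rows: list[dict] = []
    liver_rows: list[dict] = []
    patient_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"p{i + 1:03d}"
        profile = str(profiles[i])
        sex = "M" if rng.random() < 0.5 else "F"
        weight = float(np.clip(rng.normal(75.0, 12.0), 45.0, 115.0))
        height = float(np.clip(rng.normal(170.0, 9.0), 148.0, 198.0))
        attrs = PatientAttributes(weight, height, sex, 4.0 * weight)
        sul_ratio = lean_body_mass_kg(attrs) / weight

        flag_nonmeasurable = bool(rng.random() < config.p_nonmeasurable_patient)
        flag_drift = bool(rng.random() < config.p_liver_drift_patient)

        liver_sulmean = float(np.clip(rng.normal(1.8, 0.08), 1.6, 2.0))
        liver_sul_sd = float(rng.uniform(0.10, 0.18))
        liver_suvmean = liver_sulmean / sul_ratio
        liver_suv_sd = liver_sul_sd / sul_ratio
        if flag_drift:
            drift_factor = float(rng.uniform(1.25, 1.45))
        else:
            drift_factor = float(1.0 + np.clip(rng.normal(0.0, 0.05), -0.15, 0.15))

        liver_rows.append({
            "patient_id": pid, "scan": "baseline",
            "liver_sulmean": liver_sulmean, "liver_sul_sd": liver_sul_sd,
            "liver_suvmean": liver_suvmean, "liver_suv_sd": liver_suv_sd,
        })
        liver_rows.append({
            "patient_id": pid, "scan": "followup",
            "liver_sulmean": liver_sulmean * drift_factor,
            "liver_sul_sd": liver_sul_sd * drift_factor,
            "liver_suvmean": liver_suvmean * drift_factor,
            "liver_suv_sd": liver_suv_sd * drift_factor,
        })

        # patient-level injected percent changes
        if profile == "responder":
            mean, sd = config.responder_change_mean_sd
            change = float(max(rng.normal(mean, sd), -99.0))
            mtv_mean, mtv_sd = config.responder_mtv_change_mean_sd
            mtv_change = float(np.clip(rng.normal(mtv_mean, mtv_sd), -95.0, 400.0))
        elif profile == "progressor":
            mean, sd = config.progressor_change_mean_sd
            change = float(max(rng.normal(mean, sd), -99.0))
            mtv_mean, mtv_sd = config.progressor_mtv_change_mean_sd
            mtv_change = float(np.clip(rng.normal(mtv_mean, mtv_sd), -90.0, 400.0))
        elif profile == "stable":
            mean, sd = config.stable_change_mean_sd
            change = float(np.clip(rng.normal(mean, sd), -24.0, 24.0))
            mtv_change = change
        else:  # complete resolution
            change = -100.0
            mtv_change = -100.0

        floor_suv = 1.5 * (liver_suvmean + 2.0 * liver_suv_sd)
        n_lesions = int(rng.integers(config.lesions_per_patient_range[0],
                                     config.lesions_per_patient_range[1] + 1))
        compartments = rng.choice(COMPARTMENTS, size=n_lesions, replace=False)

        for j in range(n_lesions):
            lid = f"{pid}_L{j + 1}"
            suvmax = float(rng.uniform(8.0, 15.0))
            peak_ratio = float(rng.uniform(0.80, 0.92))
            mean_ratio = float(rng.uniform(0.55, 0.70))
            suvpeak = suvmax * peak_ratio
            if flag_nonmeasurable:
                # small-lesion partial-volume regime: peak below the liver floor
                suvpeak = float(rng.uniform(0.5, 0.9)) * floor_suv
                suvmax = suvpeak / peak_ratio
            elif suvpeak < 1.05 * floor_suv:
                suvpeak = 1.05 * floor_suv
                suvmax = suvpeak / peak_ratio
            sulpeak = suvpeak * sul_ratio
            suvmean = suvmax * mean_ratio
            mtv_cm3 = float(np.clip(rng.lognormal(1.2, 0.6), 0.5, 60.0))
            diameter = _equivalent_diameter_mm(mtv_cm3) * float(rng.uniform(1.0, 1.4))

            lesion_rows.append({
                "patient_id": pid, "scan": "baseline", "lesion_id": lid,
                "compartment": str(compartments[j]), "suvmax": suvmax,
                "suvmean": suvmean, "suvpeak": suvpeak, "sulpeak": sulpeak,
                "mtv_cm3": mtv_cm3, "tlg": mtv_cm3 * suvmean,
                "longest_diameter_mm": diameter, "is_new": False,
                "resolved": False,
            })

            if profile == "complete":
                f_suvmax = 0.8 * liver_suvmean * drift_factor
                row = {
                    "suvmax": f_suvmax, "suvmean": 0.8 * f_suvmax,
                    "suvpeak": 0.9 * f_suvmax,
                    "sulpeak": 0.9 * f_suvmax * sul_ratio,
                    "mtv_cm3": 0.0, "tlg": 0.0, "longest_diameter_mm": 0.0,
                    "resolved": True,
                }
            else:
                scale = 1.0 + change / 100.0
                mtv_f = mtv_cm3 * max(1.0 + mtv_change / 100.0, 0.0)
                row = {
                    "suvmax": suvmax * scale, "suvmean": suvmean * scale,
                    "suvpeak": suvpeak * scale, "sulpeak": sulpeak * scale,
                    "mtv_cm3": mtv_f, "tlg": mtv_f * suvmean * scale,
                    "longest_diameter_mm": diameter
                    * max(1.0 + mtv_change / 100.0, 0.0) ** (1.0 / 3.0),
                    "resolved": False,
                }
            lesion_rows.append({
                "patient_id": pid, "scan": "followup", "lesion_id": lid,
                "compartment": str(compartments[j]), "is_new": False, **row,
            })

        if profile == "progressor" and rng.random() < config.p_new_lesion_in_progressor:
            new_compartment = str(rng.choice(COMPARTMENTS))
            suvmax = float(rng.uniform(4.0, 8.0))
            mtv_cm3 = float(np.clip(rng.lognormal(0.3, 0.5), 0.3, 10.0))
            suvmean = 0.6 * suvmax
            lesion_rows.append({
                "patient_id": pid, "scan": "followup",
                "lesion_id": f"{pid}_new1", "compartment": new_compartment,
                "suvmax": suvmax, "suvmean": suvmean, "suvpeak": 0.85 * suvmax,
                "sulpeak": 0.85 * suvmax * sul_ratio, "mtv_cm3": mtv_cm3,
                "tlg": mtv_cm3 * suvmean,
                "longest_diameter_mm": _equivalent_diameter_mm(mtv_cm3),
                "is_new": True, "resolved": False,
            })

        patient_rows.append({
            "patient_id": pid, "sex": sex, "weight_kg": weight,
            "height_cm": height, "injected_mbq": 4.0 * weight,
            "truth_class": profile,
            "truth_dichotomy": "PD" if profile == "progressor" else "DC",
            "truth_change_pct": change, "truth_mtv_change_pct": mtv_change,
            "flag_nonmeasurable": flag_nonmeasurable,
            "flag_liver_drift": flag_drift,
        })

    lesions = pd.DataFrame(lesion_rows, columns=LESION_COLUMNS)
    patients = pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS)
    liver = pd.DataFrame(liver_rows, columns=LIVER_COLUMNS)
    return lesions, patients, liver


def generate_survival(
    groups: pd.DataFrame,
    hazard_dc: float,
    hazard_pd: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    endpoint: str = "PFS",
) -> pd.DataFrame:
    """Exponential event times with group-specific hazards (per month).

    ``groups`` needs columns ``patient_id`` and ``group`` (DC/PD).
    Censoring times are independent exponentials with rate
    ``hazard * censor_rate / (1 - censor_rate)``, which makes the expected
    censored fraction equal to ``censor_rate``.
    """
    if not (hazard_dc > 0 and hazard_pd > 0):
        raise ValueError("hazards must be > 0")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in groups.iterrows():
        hazard = hazard_dc if str(rec["group"]) == "DC" else hazard_pd
        event_time = float(rng.exponential(1.0 / hazard))
        if censor_rate > 0:
            censor_hazard = hazard * censor_rate / (1.0 - censor_rate)
            censor_time = float(rng.exponential(1.0 / censor_hazard))
        else:
            censor_time = math.inf
        rows.append({
            "patient_id": rec["patient_id"],
            "time_months": min(event_time, censor_time),
            "event": event_time <= censor_time,
            "group": str(rec["group"]),
            "endpoint": endpoint,
        })
    return pd.DataFrame(
        rows, columns=["patient_id", "time_months", "event", "group", "endpoint"]
    )


# ---------------------------------------------------------------------------
# voxel phantoms


@dataclass(frozen=True)
class SphereLesion:
    """A spherical lesion: center (mm), radius (mm) and uptake level (SUV)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    suv_level: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a simple PET phantom: background, liver sphere, lesions."""

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    liver_center_mm: tuple[float, float, float] = (60.0, 60.0, 60.0)
    liver_radius_mm: float = 22.0
    liver_suv: float = 2.0
    lesions: tuple[SphereLesion, ...] = ()

    def __post_init__(self) -> None:
        if self.liver_radius_mm <= 0:
            raise ValueError("liver radius must be > 0")
        self._check_inside(self.liver_center_mm, self.liver_radius_mm, "liver")
        for idx, lesion in enumerate(self.lesions):
            if lesion.radius_mm <= 0:
                raise ValueError(f"lesion {idx} radius must be > 0")
            self._check_inside(lesion.center_mm, lesion.radius_mm, f"lesion {idx}")

    def _check_inside(self, center, radius, what: str) -> None:
        for axis in range(3):
            extent = (self.grid_shape[axis] - 1) * self.spacing_mm[axis]
            if center[axis] - radius < 0 or center[axis] + radius > extent:
                raise ValueError(
                    f"{what} sphere (center {center}, radius {radius} mm) "
                    f"extends outside the grid on axis {axis}"
                )


@dataclass(frozen=True)
class ResponseProfile:
    """Per-lesion percent changes plus follow-up-only new lesions and liver drift."""

    changes_pct: dict[int, float] = field(default_factory=dict)
    new_lesions: tuple[SphereLesion, ...] = ()
    liver_drift_pct: float = 0.0


def _paint_sphere(values, labels, spec: PhantomSpec, center, radius, level, label):
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)],
        indexing="ij",
    )
    inside = sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2 + 1e-9
    values[inside] = level
    labels[inside] = label


def _render(spec: PhantomSpec, lesion_levels, extra_lesions, liver_level,
            rng, noise_frac) -> tuple[VoxelVolume, np.ndarray]:
    values = np.full(spec.grid_shape, spec.background_suv, dtype=float)
    labels = np.zeros(spec.grid_shape, dtype=int)
    _paint_sphere(values, labels, spec, spec.liver_center_mm,
                  spec.liver_radius_mm, liver_level, 1)
    for idx, (lesion, level) in enumerate(zip(spec.lesions, lesion_levels)):
        _paint_sphere(values, labels, spec, lesion.center_mm, lesion.radius_mm,
                      level, 2 + idx)
    for idx, lesion in enumerate(extra_lesions):
        _paint_sphere(values, labels, spec, lesion.center_mm, lesion.radius_mm,
                      lesion.suv_level, 2 + len(spec.lesions) + idx)
    if noise_frac > 0:
        values = values * (1.0 + noise_frac * rng.standard_normal(values.shape))
        values = np.clip(values, 0.0, None)
    return VoxelVolume(values, spec.spacing_mm, Unit.SUV), labels


def generate_phantom_pair(
    spec: PhantomSpec,
    profile: ResponseProfile,
    seed: int = 0,
    noise_frac: float = 0.05,
) -> tuple[tuple[VoxelVolume, np.ndarray], tuple[VoxelVolume, np.ndarray]]:
    """Baseline and follow-up phantom volumes with integer label masks.

    Follow-up lesion levels are ``baseline_level * (1 + change/100)``,
    floored at the background level (a lesion cannot become colder than
    surrounding tissue; a -100 % change dissolves it into background).
    New lesions appear only in the follow-up labels, with fresh IDs after
    the baseline lesions.  Noise is multiplicative Gaussian
    (``noise_frac`` of the local level); ``noise_frac=0`` is exact.
    """
    for idx in profile.changes_pct:
        if not 0 <= idx < len(spec.lesions):
            raise ValueError(
                f"response profile references lesion {idx}, but the spec has "
                f"{len(spec.lesions)} lesions"
            )
    for lesion in profile.new_lesions:
        spec._check_inside(lesion.center_mm, lesion.radius_mm, "new lesion")
    rng = np.random.default_rng(seed)
    base_levels = [lesion.suv_level for lesion in spec.lesions]
    follow_levels = [
        max(level * (1.0 + profile.changes_pct.get(idx, 0.0) / 100.0),
            spec.background_suv)
        for idx, level in enumerate(base_levels)
    ]
    liver_follow = spec.liver_suv * (1.0 + profile.liver_drift_pct / 100.0)
    baseline = _render(spec, base_levels, (), spec.liver_suv, rng, noise_frac)
    followup = _render(spec, follow_levels, profile.new_lesions, liver_follow,
                       rng, noise_frac)
    return baseline, followup
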