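"""Core value types shared across quantification, screening and classification."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Unit(str, enum.Enum):
    """Physical unit of a voxel grid."""

    ACTIVITY = "activity_kbq_ml"   # decay-corrected activity concentration
    SUV = "suv"                    # body-weight standardized uptake value
    SUL = "sul"                    # lean-body-mass (or BSA surrogate) SUV


class Status(str, enum.Enum):
    OK = "ok"
    NOT_AVAILABLE = "not_available"    # metric cannot be measured (n.a.)
    NOT_COMPARABLE = "not_comparable"  # baseline/follow-up liver drift (n.c.)


class Category(str, enum.Enum):
    """Metabolic response category."""

    CMR = "CMR"  # complete metabolic response
    PMR = "PMR"  # partial metabolic response
    SMD = "SMD"  # stable metabolic disease
    PMD = "PMD"  # progressive metabolic disease


class Dichotomy(str, enum.Enum):
    DC = "DC"  # disease control = CMR | PMR | SMD
    PD = "PD"  # progressive disease = PMD


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D voxel grid with millimetre spacing and a tagged unit.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; must be finite.
    spacing : tuple of float
        Voxel edge lengths in mm along each axis; all > 0.
    unit : Unit
        What the values represent (activity concentration, SUV or SUL).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    unit: Unit = Unit.SUV

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("voxel values must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "spacing", spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive mm values, got {spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class PatientAttributes:
    """Body attributes needed for SUV/SUL normalization."""

    weight_kg: float
    height_cm: float
    sex: str  # "M" or "F"
    injected_activity_mbq: float

    def __post_init__(self) -> None:
        for name in ("weight_kg", "height_cm", "injected_activity_mbq"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class LesionMeasurement:
    """Uptake metrics of one lesion at one timepoint.

    ``tlg`` is always ``mtv_cm3 * suvmean`` (total lesion glycolysis);
    ``resolved`` records the reader-level call that uptake is
    indistinguishable from surrounding normal tissue.
    """

    lesion_id: str
    compartment: str
    suvmax: float
    suvmean: float
    suvpeak: float
    sulpeak: float
    mtv_cm3: float
    tlg: float
    longest_diameter_mm: float
    resolved: bool = False

    def __post_init__(self) -> None:
        for name in ("suvmax", "suvmean", "suvpeak", "sulpeak", "mtv_cm3",
                     "tlg", "longest_diameter_mm"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if np.isfinite(self.suvpeak) and self.suvpeak > self.suvmax + 1e-9:
            raise ValueError("suvpeak cannot exceed suvmax")


@dataclass(frozen=True)
class LiverReference:
    """Mean and population SD of SUL/SUV over a spherical liver ROI (3 cm default)."""

    sulmean: float
    sul_sd: float
    suvmean: float
    suv_sd: float = 0.0
    sphere_diameter_mm: float = 30.0
    center_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.sul_sd < 0 or self.suv_sd < 0:
            raise ValueError("liver SDs must be >= 0")


@dataclass(frozen=True)
class ApplicabilityStatus:
    """Whether a criteria set can be applied to a patient, and why not."""

    status: Status
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status is not Status.OK and not self.reason:
            raise ValueError("non-ok status requires a reason")

    @property
    def ok(self) -> bool:
        return self.status is Status.OK


@dataclass(frozen=True)
class ResponseResult:
    """Per-patient outcome of one criteria set under one target-selection mode."""

    patient_id: str
    criteria: str
    selection: str                      # "hottest" or "all"
    applicability: ApplicabilityStatus
    category: Category | None = None
    dichotomy: Dichotomy | None = None
    percent_change: float | None = None
    target_baseline_ids: tuple[str, ...] = field(default_factory=tuple)
    target_followup_ids: tuple[str, ...] = field(default_factory=tuple)
    new_lesion: bool = False

    def __post_init__(self) -> None:
        if self.category is not None:
            expected = Dichotomy.PD if self.category is Category.PMD else Dichotomy.DC
            if self.dichotomy is not expected:
                raise ValueError("dichotomy inconsistent with category")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in months, event flag and DC/PD group."""

    patient_id: str
    time_months: float
    event: bool
    group: Dichotomy

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time_months) and self.time_months >= 0):
            raise ValueError("time_months must be finite and >= 0")
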