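"""PET uptake quantification: SUV/SUL conversion, SUVpeak, MTV, TLG, liver ROI.

Conventions
-----------
* SUV = activity concentration / (injected activity / body weight), with
  tissue density taken as 1 g/mL.
* SUVpeak is the maximum, over candidate sphere centers placed on voxel
  centers inside the lesion mask, of the mean of all voxels whose centers
  lie within a 12-mm-diameter sphere (~1 cm^3).  The sphere may extend
  beyond the lesion mask; voxels outside the grid do not contribute.
* MTV uses a relative threshold (default 42 % of lesion SUVmax) and keeps
  the 26-connected component(s) touching the seed mask.
* The liver reference is the mean and population SD (divisor n) over a
  3-cm sphere, so the "mean + 2 SD" background floor is reproducible.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from petresponse.types import LiverReference, PatientAttributes, Unit, VoxelVolume

SUL_METHODS = ("lbm_janmahasatian", "lbm_james", "bsa")


def to_suv(volume: VoxelVolume, attrs: PatientAttributes) -> VoxelVolume:
    """Convert an activity-concentration grid (kBq/mL) to body-weight SUV.

    SUV = c[kBq/mL] / (injected[kBq] / weight[g]); with 1 g/mL density this
    reduces to c * weight_kg / injected_MBq.  A grid already tagged as SUV
    is returned unchanged with a warning.
    """
    if volume.unit is Unit.SUV:
        warnings.warn("volume is already in SUV units; returning unchanged")
        return volume
    if volume.unit is not Unit.ACTIVITY:
        raise ValueError(f"cannot convert unit {volume.unit} to SUV")
    factor = attrs.weight_kg / attrs.injected_activity_mbq
    return VoxelVolume(volume.values * factor, volume.spacing, Unit.SUV)


def lean_body_mass_kg(attrs: PatientAttributes, method: str = "lbm_janmahasatian") -> float:
    """Normalizing mass in kg for SUL: LBM (two formulas) or a BSA surrogate.

    * ``lbm_janmahasatian``: sex-specific BMI-based lean body mass.
    * ``lbm_james``: the classical James formula.
    * ``bsa``: Du Bois body surface area mapped to a mass equivalent by
      standard-person scaling (70 kg per 1.73 m^2).
    """
    w, h = attrs.weight_kg, attrs.height_cm
    if method == "lbm_janmahasatian":
        bmi = w / (h / 100.0) ** 2
        if attrs.sex == "M":
            return 9270.0 * w / (6680.0 + 216.0 * bmi)
        return 9270.0 * w / (8780.0 + 244.0 * bmi)
    if method == "lbm_james":
        if attrs.sex == "M":
            return 1.10 * w - 128.0 * (w / h) ** 2
        return 1.07 * w - 148.0 * (w / h) ** 2
    if method == "bsa":
        bsa_m2 = 0.007184 * w**0.425 * h**0.725
        return 70.0 * bsa_m2 / 1.73
    raise ValueError(f"unknown SUL method {method!r}; choose from {SUL_METHODS}")


def suv_to_sul(suv, attrs: PatientAttributes, method: str = "lbm_janmahasatian"):
    """Rescale SUV to SUL: SUL = SUV * normalizer / weight.

    Accepts a scalar, an array, or a :class:`VoxelVolume` (returned with
    the unit tag set to SUL).
    """
    if attrs.height_cm is None or attrs.sex is None:  # pragma: no cover - dataclass enforces
        raise ValueError("SUL normalization requires height_cm and sex")
    ratio = lean_body_mass_kg(attrs, method) / attrs.weight_kg
    if isinstance(suv, VoxelVolume):
        if suv.unit is not Unit.SUV:
            raise ValueError("suv_to_sul expects a volume in SUV units")
        return VoxelVolume(suv.values * ratio, suv.spacing, Unit.SUL)
    return np.asarray(suv, dtype=float) * ratio if np.ndim(suv) else float(suv) * ratio


def _sphere_offsets(spacing: tuple[float, ...], diameter_mm: float) -> np.ndarray:
    """Integer voxel offsets whose centers lie within a sphere of the given diameter."""
    radius = diameter_mm / 2.0
    reach = [int(math.floor(radius / s)) for s in spacing]
    axes = [np.arange(-r, r + 1) for r in reach]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    d2 = (ii * spacing[0]) ** 2 + (jj * spacing[1]) ** 2 + (kk * spacing[2]) ** 2
    keep = d2 <= radius**2 + 1e-9
    return np.stack([ii[keep], jj[keep], kk[keep]], axis=1)


def suv_peak(
    volume: VoxelVolume,
    lesion_mask: np.ndarray,
    sphere_diameter_mm: float = 12.0,
) -> float:
    """Sphere-averaged peak uptake within a lesion.

    Candidate centers are the voxel centers inside ``lesion_mask``; each
    candidate's value is the mean of grid voxels whose centers fall within
    the sphere (clipped at the grid boundary).  Returns the maximum.
    """
    mask = np.asarray(lesion_mask, dtype=bool)
    if mask.shape != volume.values.shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("lesion mask is empty")
    if sphere_diameter_mm > min(
        n * s for n, s in zip(volume.values.shape, volume.spacing)
    ):
        raise ValueError("sphere diameter exceeds grid extent")
    offsets = _sphere_offsets(volume.spacing, sphere_diameter_mm)
    kernel_shape = offsets.max(axis=0) - offsets.min(axis=0) + 1
    kernel = np.zeros(kernel_shape, dtype=float)
    kernel[tuple((offsets - offsets.min(axis=0)).T)] = 1.0
    sums = ndimage.convolve(volume.values, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(
        np.ones_like(volume.values), kernel, mode="constant", cval=0.0
    )
    peak_map = sums / counts
    return float(peak_map[mask].max())


def mtv(
    volume: VoxelVolume,
    seed_mask: np.ndarray,
    relative_pct_of_suvmax: float = 42.0,
    absolute_floor: float | None = None,
) -> tuple[float, np.ndarray]:
    """Metabolic tumor volume by threshold-and-grow delineation.

    The threshold is ``relative_pct_of_suvmax`` percent of the maximum
    uptake inside the seed mask (optionally raised to ``absolute_floor``);
    the delineation keeps the 26-connected components of supra-threshold
    voxels that touch the seed.  Returns (MTV in cm^3, delineation mask).
    """
    seed = np.asarray(seed_mask, dtype=bool)
    if not seed.any():
        raise ValueError("seed mask is empty")
    suvmax = float(volume.values[seed].max())
    threshold = suvmax * relative_pct_of_suvmax / 100.0
    if absolute_floor is not None:
        threshold = max(threshold, absolute_floor)
    above = volume.values >= threshold
    if not above.any():
        return 0.0, np.zeros_like(seed)
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    seed_labels = np.unique(labels[seed])
    seed_labels = seed_labels[seed_labels > 0]
    if seed_labels.size == 0:
        return 0.0, np.zeros_like(seed)
    delineation = np.isin(labels, seed_labels)
    volume_cm3 = delineation.sum() * volume.voxel_volume_mm3 / 1000.0
    return float(volume_cm3), delineation


def tlg(mtv_cm3: float, suvmean: float) -> float:
    """Total lesion glycolysis = MTV x SUVmean (exact product)."""
    if mtv_cm3 < 0 or suvmean < 0:
        raise ValueError("MTV and SUVmean must be >= 0")
    return mtv_cm3 * suvmean


def _sphere_mask(
    shape: tuple[int, ...],
    spacing: tuple[float, ...],
    center_mm: tuple[float, ...],
    diameter_mm: float,
) -> np.ndarray:
    radius = diameter_mm / 2.0
    for axis in range(3):
        extent = (shape[axis] - 1) * spacing[axis]
        if center_mm[axis] - radius < 0 or center_mm[axis] + radius > extent:
            raise ValueError(
                f"sphere of diameter {diameter_mm} mm at {center_mm} is clipped "
                f"by the grid boundary on axis {axis}"
            )
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= radius**2 + 1e-9


def liver_reference(
    sul_volume: VoxelVolume,
    suv_volume: VoxelVolume,
    liver_center_mm: tuple[float, float, float],
    sphere_diameter_mm: float = 30.0,
) -> LiverReference:
    """Liver background statistics over a 3-cm sphere.

    Mean and population SD (divisor n) of both the SUL and the SUV grid
    over the sphere; errors out if the sphere is clipped by the grid.
    """
    mask = _sphere_mask(
        suv_volume.values.shape, suv_volume.spacing, liver_center_mm, sphere_diameter_mm
    )
    sul_vals = sul_volume.values[mask]
    suv_vals = suv_volume.values[mask]
    return LiverReference(
        sulmean=float(sul_vals.mean()),
        sul_sd=float(sul_vals.std(ddof=0)),
        suvmean=float(suv_vals.mean()),
        suv_sd=float(suv_vals.std(ddof=0)),
        sphere_diameter_mm=float(sphere_diameter_mm),
        center_mm=tuple(float(c) for c in liver_center_mm),
    )


def longest_diameter(
    delineation_mask: np.ndarray,
    spacing: tuple[float, float, float],
    hull_threshold: int = 300,
) -> float:
    """Longest distance (mm) between any two voxel centers of a lesion mask.

    Small masks use all-pairs brute force; larger ones restrict the pair
    search to the convex hull vertices (the diameter of a finite point set
    is attained on its hull), falling back to brute force for degenerate
    (coplanar/collinear) geometries.
    """
    mask = np.asarray(delineation_mask, dtype=bool)
    if not mask.any():
        raise ValueError("delineation mask is empty")
    coords = np.argwhere(mask) * np.asarray(spacing, dtype=float)
    if coords.shape[0] == 1:
        return 0.0
    if coords.shape[0] > hull_threshold:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except QhullError:
            pass
    return float(pdist(coords).max())


def measure_scan(
    suv_volume: VoxelVolume,
    labels: np.ndarray,
    attrs: PatientAttributes,
    liver_center_mm: tuple[float, float, float],
    sul_method: str = "lbm_janmahasatian",
    patient_id: str = "p001",
    scan: str = "baseline",
    peak_sphere_mm: float = 12.0,
    mtv_relative_pct: float = 42.0,
):
    """Quantify every lesion of one scan into the lesion-table schema.

    ``labels`` is an integer mask (0 background, 1 liver, >=2 lesions with
    IDs stable across scans).  Returns ``(lesions DataFrame, LiverReference)``.
    A lesion is marked ``resolved`` when its SUVmax is within mean + 2 SD
    of the unlabelled background voxels (uptake indistinguishable from
    surrounding normal tissue).
    """
    import pandas as pd

    labels = np.asarray(labels)
    if labels.shape != suv_volume.values.shape:
        raise ValueError("labels shape does not match volume")
    sul_volume = suv_to_sul(suv_volume, attrs, sul_method)
    liver = liver_reference(sul_volume, suv_volume, liver_center_mm)
    background = suv_volume.values[labels == 0]
    bg_ceiling = float(background.mean() + 2.0 * background.std(ddof=0))

    rows = []
    for label_id in sorted(int(v) for v in np.unique(labels) if v >= 2):
        mask = labels == label_id
        suvmax = float(suv_volume.values[mask].max())
        mtv_cm3, delineation = mtv(suv_volume, mask, mtv_relative_pct)
        region = delineation if delineation.any() else mask
        suvmean = float(suv_volume.values[region].mean())
        suvpeak = suv_peak(suv_volume, mask, peak_sphere_mm)
        sulpeak = suv_peak(sul_volume, mask, peak_sphere_mm)
        rows.append({
            "patient_id": patient_id,
            "scan": scan,
            "lesion_id": f"L{label_id}",
            "compartment": f"region_{label_id}",
            "suvmax": suvmax,
            "suvmean": suvmean,
            "suvpeak": suvpeak,
            "sulpeak": sulpeak,
            "mtv_cm3": mtv_cm3,
            "tlg": tlg(mtv_cm3, suvmean),
            "longest_diameter_mm": longest_diameter(region, suv_volume.spacing),
            "is_new": False,
            "resolved": suvmax <= bg_ceiling,
        })
    return pd.DataFrame(rows), liver
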