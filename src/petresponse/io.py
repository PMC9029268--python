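"""File I/O: NIfTI volumes via nibabel, CSV tables, YAML configs, JSON reports.

CSV and JSON writers use fixed float formatting and sorted keys so that a
rerun with the same config and seed produces byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from petresponse.types import Unit, VoxelVolume

FLOAT_FORMAT = "%.10g"


def save_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a voxel grid as NIfTI with the spacing encoded in the affine."""
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path, unit: Unit = Unit.SUV) -> VoxelVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(np.asarray(img.dataobj, dtype=float), spacing, unit)


def save_labels(labels: np.ndarray, spacing, path: str | Path) -> None:
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def load_labels(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=int)


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    return loaded or {}


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
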