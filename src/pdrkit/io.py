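"""NIfTI-1 and CSV input/output.

Volumes are written as float32 NIfTI-1 (ADC in 1e-6 mm^2/s), masks as
uint8, truth labels as uint8; voxel spacing lives in the affine/zooms and
round-trips to 1e-6 mm.  Cohort tables are CSV with the PatientRecord
columns; a schema error names any missing column.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .phantom import TruthLabels
from .volumes import ImageVolume, ParameterError, RoiMask, SchemaError

SPACING_TOL_MM = 1e-6


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0]).astype(np.float64)
    return aff


def write_volume(volume: ImageVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.values.astype(np.float32),
                          _affine(volume.voxel_spacing_mm))
    img.header.set_zooms(volume.voxel_spacing_mm)
    nib.save(img, str(path))
    return path


def read_volume(path, modality: str) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ParameterError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return ImageVolume(data, spacing, modality)


def write_mask(mask: RoiMask, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.values.astype(np.uint8),
                          _affine(mask.voxel_spacing_mm))
    img.header.set_zooms(mask.voxel_spacing_mm)
    nib.save(img, str(path))
    return path


def read_mask(path, label: str) -> RoiMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return RoiMask(data > 0, spacing, label)


def write_truth(truth: TruthLabels, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(truth.labels.astype(np.uint8),
                          _affine(truth.voxel_spacing_mm))
    img.header.set_zooms(truth.voxel_spacing_mm)
    nib.save(img, str(path))
    return path


def read_truth(path) -> TruthLabels:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.uint8)
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return TruthLabels(labels=data, voxel_spacing_mm=spacing)


def check_case_spacing(volumes: dict[str, ImageVolume]) -> None:
    """All modalities of one case must share shape and spacing."""
    mods = sorted(volumes)
    first = volumes[mods[0]]
    for m in mods[1:]:
        v = volumes[m]
        if v.shape != first.shape:
            raise ParameterError(
                f"shape mismatch between {mods[0]} and {m}: {first.shape} vs {v.shape}")
        for a, b in zip(first.voxel_spacing_mm, v.voxel_spacing_mm):
            if abs(a - b) > SPACING_TOL_MM:
                raise ParameterError(
                    f"voxel spacing mismatch between {mods[0]} and {m}: "
                    f"{first.voxel_spacing_mm} vs {v.voxel_spacing_mm}")


def write_cohort(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    return df


def read_cohort_sav(path, column_map: dict[str, str]) -> pd.DataFrame:
    """Optional importer for an SPSS .sav patient table.

    The file's column layout is not standardised, so an explicit
    ``column_map`` from source column names to the cohort schema is
    required.  Needs the optional ``pyreadstat`` dependency.
    """
    try:
        import pyreadstat  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading SPSS .sav files requires the optional 'pyreadstat' "
            "package") from exc
    df, _meta = pyreadstat.read_sav(str(path))
    df = df.rename(columns=dict(column_map))
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"column map leaves cohort columns unmapped: {missing}")
    return df[COHORT_COLUMNS]
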