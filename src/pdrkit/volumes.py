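"""Shared in-memory containers for modality volumes and ROI masks.

All images in the pipeline live on a regular 3-D lattice with physical
voxel spacing in millimetres.  The first lattice axis is the left-right
(patient) axis; the midsagittal plane is the central plane of that axis
and mirror operations reflect across it.  ADC volumes carry physical
units of 1e-6 mm^2/s; FLAIR, b1000 and T2*/SWI are unitless signal
levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("FLAIR", "B1000", "ADC", "T2STAR")
ROI_LABELS = ("IPH", "LESION", "PHE", "PDR", "MIRROR", "BRAIN")


class PdrkitError(Exception):
    """Base class for pipeline errors."""


class GeometryError(PdrkitError):
    """Phantom geometry does not fit the grid or crosses the midline."""


class ParameterError(PdrkitError):
    """Invalid parameter value."""


class RegistrationError(PdrkitError):
    """Registration cannot be computed (e.g. zero-variance image)."""


class ContractError(PdrkitError):
    """A pre-condition between ROIs is violated (e.g. IPH not inside lesion)."""


class SchemaError(PdrkitError):
    """A cohort table is missing required columns."""


class MirrorError(PdrkitError):
    """Too few mirror voxels survive the exclusion rules."""


@dataclass
class ImageVolume:
    """One modality as a 3-D scalar lattice with voxel spacing and a tag."""

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ParameterError("volume must be 3-D")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ParameterError("voxel spacing must be three positive values")
        if self.modality not in MODALITIES:
            raise ParameterError(f"unknown modality {self.modality!r}")
        if self.modality == "ADC" and float(self.values.min()) < 0:
            raise ParameterError("ADC values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))


@dataclass
class RoiMask:
    """A binary region of interest on the same lattice as its parent volume.

    ``flags`` records non-fatal conditions raised while the mask was built
    (e.g. an empty segmentation result).
    """

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    label: str
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ParameterError("mask must be 3-D")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ParameterError("voxel spacing must be positive")
        if self.label not in ROI_LABELS:
            raise ParameterError(f"unknown ROI label {self.label!r}")
        self.flags = tuple(self.flags)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.values.any())


def check_same_grid(a: ImageVolume | RoiMask, b: ImageVolume | RoiMask,
                    tol_mm: float = 1e-6) -> None:
    """Raise if two lattices differ in shape or spacing (beyond ``tol_mm``)."""
    if a.shape != b.shape:
        raise ParameterError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    for sa, sb in zip(a.voxel_spacing_mm, b.voxel_spacing_mm):
        if abs(sa - sb) > tol_mm:
            raise ParameterError(
                f"voxel spacing mismatch: {a.voxel_spacing_mm} vs {b.voxel_spacing_mm}")


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
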