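"""Synthetic multimodal MRI phantoms of hyperacute intracerebral hemorrhage.

A phantom is a brain-shaped ellipsoid containing, in one hemisphere, an
intraparenchymal hematoma (IPH, a solid ellipsoid), a perihematomal edema
shell (PHE) of constant Euclidean thickness around it, and optionally a
thin perihematomal diffusion-restriction rim (PDR) immediately outside the
PHE's outer border.  Four co-registered modality volumes are rendered:

* ``ADC``    -- per-voxel apparent diffusion coefficient in 1e-6 mm^2/s,
  drawn per compartment from a split-normal distribution parameterised by
  the compartment's median and interquartile range (separate scales below
  and above the median, so asymmetric IQRs are honoured exactly).
* ``FLAIR``  -- markedly hyperintense over the edema but not over the
  PDR; the clot itself is only mildly hyperintense (hyperacute blood),
  so the clot/edema transition on FLAIR marks the true clot border.
* ``B1000``  -- hyperintense over the PDR (restricted diffusion is bright
  on diffusion-weighted images).
* ``T2STAR`` -- hypointense clot, dilated ("blooming") by a configurable
  volume fraction, emulating the known susceptibility overestimation of
  hematoma size.

The background brain is left-right symmetric, so the contralateral mirror
region of any one-hemisphere lesion samples statistically identical
tissue.  Regeneration from the same (spec, seed) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .volumes import (
    MODALITIES,
    GeometryError,
    ImageVolume,
    ParameterError,
)

# Truth label codes
OUTSIDE = 0
BACKGROUND = 1
IPH = 2
PHE = 3
PDR = 4

LABEL_NAMES = {
    OUTSIDE: "outside_brain",
    BACKGROUND: "background_brain",
    IPH: "iph",
    PHE: "phe",
    PDR: "pdr",
}

# z-score of the 75th percentile of the standard normal
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class CompartmentSpec:
    """Signal model of one tissue compartment.

    ``adc_median`` / ``adc_iqr`` are in 1e-6 mm^2/s; the other levels are
    unitless signal intensities.
    """

    name: str
    adc_median: float
    adc_iqr: tuple[float, float]
    flair_level: float
    b1000_level: float
    t2star_level: float

    def __post_init__(self) -> None:
        p25, p75 = self.adc_iqr
        if not (p25 <= self.adc_median <= p75):
            raise ParameterError(
                f"{self.name}: IQR must bracket the median "
                f"({p25} <= {self.adc_median} <= {p75} fails)")
        for v in (p25, self.adc_median, p75):
            if not (0 < v <= 4000):
                raise ParameterError(f"{self.name}: ADC {v} outside (0, 4000]")


def default_compartments() -> dict[str, CompartmentSpec]:
    """Compartment signal models for the hyperacute window.

    IPH/PHE/PDR ADC medians and IQRs are the values observed across
    hyperacute hemorrhage patients; background brain is set to normal
    deep white/grey matter ADC so the mirror-region reference behaves
    like healthy contralateral tissue.
    """
    return {
        "BACKGROUND_BRAIN": CompartmentSpec(
            "BACKGROUND_BRAIN", 800.0, (760.0, 840.0),
            flair_level=100.0, b1000_level=100.0, t2star_level=100.0),
        "IPH": CompartmentSpec(
            "IPH", 789.0, (710.0, 890.0),
            flair_level=105.0, b1000_level=110.0, t2star_level=40.0),
        "PHE": CompartmentSpec(
            "PHE", 1030.0, (948.0, 1110.0),
            flair_level=180.0, b1000_level=90.0, t2star_level=100.0),
        "PDR": CompartmentSpec(
            "PDR", 624.5, (598.5, 670.0),
            flair_level=105.0, b1000_level=160.0, t2star_level=100.0),
    }


def default_noise_sd() -> dict[str, float]:
    return {"FLAIR": 6.0, "B1000": 6.0, "ADC": 20.0, "T2STAR": 6.0}


@dataclass
class PhantomSpec:
    """Full description of one phantom; geometry coordinates are in mm.

    The midsagittal plane is the central plane of the first grid axis;
    the lesion (IPH plus all shells) must lie strictly inside one
    hemisphere and inside the brain ellipsoid.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_radii_mm: tuple[float, float, float] = (56.0, 56.0, 36.0)
    iph_center_mm: tuple[float, float, float] = (38.0, 63.0, 39.0)
    iph_radii_mm: tuple[float, float, float] = (15.0, 13.0, 13.0)
    phe_thickness_mm: float = 6.0
    pdr_present: bool = True
    pdr_thickness_mm: float = 2.0
    compartments: dict[str, CompartmentSpec] = field(default_factory=default_compartments)
    noise_sd: dict[str, float] = field(default_factory=default_noise_sd)
    t2star_blooming_fraction: float = 0.20
    rigid_offset_mm: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if any(n <= 0 for n in self.grid_shape):
            raise ParameterError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ParameterError("voxel spacing must be positive")
        if any(r <= 0 for r in self.iph_radii_mm):
            raise ParameterError("IPH radii must be positive")
        if self.phe_thickness_mm < 0 or self.pdr_thickness_mm < 0:
            raise ParameterError("shell thicknesses must be non-negative")
        if self.t2star_blooming_fraction < 0:
            raise ParameterError("blooming fraction must be non-negative")
        for m, sd in self.noise_sd.items():
            if sd < 0:
                raise ParameterError(f"negative noise SD for {m}")
        for m in self.rigid_offset_mm:
            if m not in MODALITIES:
                raise ParameterError(f"rigid offset for unknown modality {m!r}")

    @property
    def midline_mm(self) -> float:
        return (self.grid_shape[0] - 1) / 2.0 * self.voxel_spacing_mm[0]


@dataclass
class TruthLabels:
    """Per-voxel ground-truth compartment labels (mutually exclusive)."""

    labels: np.ndarray  # uint8, codes above
    voxel_spacing_mm: tuple[float, float, float]

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != OUTSIDE


@dataclass
class PhantomCase:
    """Co-registered modality volumes plus the truth that generated them."""

    volumes: dict[str, ImageVolume]
    truth: TruthLabels
    spec: PhantomSpec
    seed: int


def _grid_coords_mm(shape, spacing):
    return np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]], spacing


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    (ii, jj, kk), sp = _grid_coords_mm(shape, spacing)
    rho = ((ii * sp[0] - center_mm[0]) / radii_mm[0]) ** 2 \
        + ((jj * sp[1] - center_mm[1]) / radii_mm[1]) ** 2 \
        + ((kk * sp[2] - center_mm[2]) / radii_mm[2]) ** 2
    return rho <= 1.0


def brain_mask_for(spec: PhantomSpec) -> np.ndarray:
    """Brain ellipsoid centred on the grid, symmetric about the midline."""
    center = tuple((n - 1) / 2.0 * s
                   for n, s in zip(spec.grid_shape, spec.voxel_spacing_mm))
    return _ellipsoid_mask(spec.grid_shape, spec.voxel_spacing_mm,
                           center, spec.brain_radii_mm)


def build_geometry(spec: PhantomSpec) -> TruthLabels:
    """Deterministic compartment geometry: IPH ellipsoid, PHE and PDR shells.

    Shells have constant Euclidean thickness, measured by the distance
    transform from the IPH surface with physical voxel spacing.  Raises
    :class:`GeometryError` if the lesion leaves the brain or touches or
    crosses the midsagittal plane.
    """
    shape, sp = spec.grid_shape, spec.voxel_spacing_mm
    iph = _ellipsoid_mask(shape, sp, spec.iph_center_mm, spec.iph_radii_mm)
    if not iph.any():
        raise GeometryError("IPH ellipsoid contains no voxels")
    dist = ndimage.distance_transform_edt(~iph, sampling=sp)
    phe = (dist > 0) & (dist <= spec.phe_thickness_mm)
    outer = spec.phe_thickness_mm
    if spec.pdr_present and spec.pdr_thickness_mm > 0:
        pdr = (dist > outer) & (dist <= outer + spec.pdr_thickness_mm)
    else:
        pdr = np.zeros(shape, bool)

    brain = brain_mask_for(spec)
    lesion_all = iph | phe | pdr
    if (lesion_all & ~brain).any():
        raise GeometryError("lesion (including shells) extends outside the brain")
    # strictly inside one hemisphere
    coords0 = np.nonzero(lesion_all)[0] * sp[0]
    mid = spec.midline_mm
    if not (np.all(coords0 < mid) or np.all(coords0 > mid)):
        raise GeometryError("lesion touches or crosses the midsagittal plane")

    labels = np.zeros(shape, np.uint8)
    labels[brain] = BACKGROUND
    labels[iph] = IPH
    labels[phe] = PHE
    labels[pdr] = PDR
    return TruthLabels(labels=labels, voxel_spacing_mm=sp)


def sample_split_normal(rng: np.random.Generator, n: int,
                        median: float, p25: float, p75: float) -> np.ndarray:
    """Draw from a two-piece normal with the given median and quartiles.

    A standard normal deviate is scaled by (median-p25)/z75 below zero and
    (p75-median)/z75 above, so the population median and both quartiles
    match the requested values exactly.
    """
    z = rng.standard_normal(n)
    lo = (median - p25) / _Z75
    hi = (p75 - median) / _Z75
    return median + z * np.where(z < 0, lo, hi)


def _bloom_mask(iph: np.ndarray, brain: np.ndarray, spacing,
                fraction: float) -> np.ndarray:
    """Dilate the clot by ``fraction`` of its volume (nearest voxels first).

    Ties in distance are broken by flat voxel index, so the result is
    deterministic.
    """
    n_extra = int(round(fraction * int(iph.sum())))
    if n_extra == 0:
        return iph.copy()
    dist = ndimage.distance_transform_edt(~iph, sampling=spacing)
    candidates = np.flatnonzero(~iph.ravel() & brain.ravel())
    order = np.lexsort((candidates, dist.ravel()[candidates]))
    chosen = candidates[order[:n_extra]]
    bloomed = iph.copy().ravel()
    bloomed[chosen] = True
    return bloomed.reshape(iph.shape)


def render_modalities(truth: TruthLabels, spec: PhantomSpec,
                      seed: int) -> dict[str, ImageVolume]:
    """Render FLAIR, b1000, ADC and T2* volumes on the truth lattice.

    ADC is drawn per compartment from the split-normal model; the other
    modalities are piecewise-constant compartment levels.  Additive
    Gaussian noise with the spec's per-modality SD is applied last, and
    ADC is clipped at zero (outside-brain air only).
    """
    rng = np.random.default_rng(seed)
    comp = spec.compartments
    labels = truth.labels
    shape = labels.shape
    code_to_comp = {BACKGROUND: "BACKGROUND_BRAIN", IPH: "IPH",
                    PHE: "PHE", PDR: "PDR"}

    adc = np.zeros(shape, np.float64)
    flair = np.zeros(shape, np.float64)
    b1000 = np.zeros(shape, np.float64)
    t2star = np.zeros(shape, np.float64)
    for code in (BACKGROUND, IPH, PHE, PDR):
        m = labels == code
        n = int(m.sum())
        if n == 0:
            continue
        c = comp[code_to_comp[code]]
        adc[m] = sample_split_normal(rng, n, c.adc_median, *c.adc_iqr)
        flair[m] = c.flair_level
        b1000[m] = c.b1000_level
        t2star[m] = c.t2star_level

    bloomed = _bloom_mask(labels == IPH, labels != OUTSIDE,
                          spec.voxel_spacing_mm, spec.t2star_blooming_fraction)
    t2star[bloomed] = comp["IPH"].t2star_level

    arrays = {"FLAIR": flair, "B1000": b1000, "ADC": adc, "T2STAR": t2star}
    out: dict[str, ImageVolume] = {}
    for mod in MODALITIES:
        arr = arrays[mod]
        sd = float(spec.noise_sd.get(mod, 0.0))
        if sd < 0:
            raise ParameterError(f"negative noise SD for {mod}")
        if sd > 0:
            arr = arr + rng.normal(0.0, sd, size=shape)
        if mod == "ADC":
            arr = np.clip(arr, 0.0, None)
        out[mod] = ImageVolume(arr.astype(np.float32),
                               spec.voxel_spacing_mm, mod)
    return out


def shift_integer(values: np.ndarray, shift_voxels: tuple[int, int, int],
                  fill: float = 0.0) -> np.ndarray:
    """Translate an array by whole voxels, filling vacated space."""
    out = np.full_like(values, fill)
    src = []
    dst = []
    for n, s in zip(values.shape, shift_voxels):
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = values[tuple(src)]
    return out


def offset_voxels(spec: PhantomSpec, modality: str) -> tuple[int, int, int]:
    """Per-modality rigid offset rounded to whole voxels."""
    off_mm = spec.rigid_offset_mm.get(modality, (0.0, 0.0, 0.0))
    return tuple(int(round(o / s))
                 for o, s in zip(off_mm, spec.voxel_spacing_mm))


def make_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Geometry plus rendering plus per-modality rigid offsets."""
    truth = build_geometry(spec)
    volumes = render_modalities(truth, spec, seed)
    for mod, vol in volumes.items():
        sv = offset_voxels(spec, mod)
        if any(sv):
            volumes[mod] = ImageVolume(shift_integer(vol.values, sv),
                                       vol.voxel_spacing_mm, mod)
    return PhantomCase(volumes=volumes, truth=truth, spec=spec, seed=int(seed))


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-serialisable form of a phantom spec (round-trips losslessly)."""
    d = asdict(spec)
    d["compartments"] = {k: asdict(v) for k, v in spec.compartments.items()}
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    comps = {k: CompartmentSpec(**{**v, "adc_iqr": tuple(v["adc_iqr"])})
             for k, v in d["compartments"].items()}
    d["compartments"] = comps
    d["rigid_offset_mm"] = {k: tuple(v)
                            for k, v in d.get("rigid_offset_mm", {}).items()}
    for key in ("grid_shape", "voxel_spacing_mm", "brain_radii_mm",
                "iph_center_mm", "iph_radii_mm"):
        d[key] = tuple(d[key])
    return PhantomSpec(**d)
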