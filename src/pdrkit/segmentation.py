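"""Automated emulation of the hemorrhage ROI procedure.

Stages, in pipeline order:

1. rigid (integer-translation) registration of each modality to the ADC
   grid by exhaustive normalised cross-correlation;
2. IPH segmentation: largest T2*-hypointense connected component,
   refined on FLAIR so the mask follows the clot border rather than the
   susceptibility "blooming" margin;
3. whole-lesion segmentation on FLAIR (hyperintense component touching
   the clot), and PHE = lesion minus IPH;
4. contralateral mirror region: the lesion reflected across the
   midsagittal plane, minus non-brain voxels and the dilated lesion;
5. PDR detection inside the PHE plus a thin outer shell: voxels that are
   BOTH hypointense on ADC (<= mirror median - f * mirror SD, default
   f = 1.5) and hyperintense on b1000 (>= mirror median + f_b * SD).

All connected-component operations use 26-connectivity.  Every numeric
threshold actually applied is emitted on the ``pdrkit.segmentation``
logger so any case's PDR call is auditable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import (
    ContractError,
    ImageVolume,
    MirrorError,
    ParameterError,
    RegistrationError,
    RoiMask,
    check_same_grid,
)
from .phantom import shift_integer

logger = logging.getLogger("pdrkit.segmentation")

_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass(frozen=True)
class RigidTransform:
    """Integer-voxel translation aligning a moving volume to a fixed one."""

    translation_voxels: tuple[int, int, int]


@dataclass(frozen=True)
class MirrorStats:
    """Reference statistics of the contralateral mirror region."""

    adc_median: float
    adc_sd: float
    b1000_median: float
    b1000_sd: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.adc_sd < 0 or self.b1000_sd < 0:
            raise ParameterError("mirror SDs must be non-negative")


def robust_sd(values: np.ndarray) -> float:
    """SD estimate 1.4826 * MAD, insensitive to a lesion in the sample."""
    v = np.asarray(values, float)
    med = np.median(v)
    return 1.4826 * float(np.median(np.abs(v - med)))


def _overlap_slices(shape, shift):
    src, dst = [], []
    for n, s in zip(shape, shift):
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    return tuple(src), tuple(dst)


def register_translation(moving: ImageVolume, fixed: ImageVolume,
                         search_radius_voxels: int = 3) -> RigidTransform:
    """Exhaustive integer-shift registration by normalised cross-correlation.

    Ties are broken by smallest shift magnitude, then lexicographic order
    (shifts are visited in that order and only strictly better scores
    replace the incumbent).
    """
    a = np.asarray(moving.values, np.float64)
    b = np.asarray(fixed.values, np.float64)
    if a.shape != b.shape:
        raise RegistrationError("volumes must share a grid shape")
    if float(a.std()) == 0.0 or float(b.std()) == 0.0:
        raise RegistrationError("zero-variance image cannot be registered")
    r = int(search_radius_voxels)
    shifts = sorted(itertools.product(range(-r, r + 1), repeat=3),
                    key=lambda s: (s[0] * s[0] + s[1] * s[1] + s[2] * s[2], s))
    best, best_ncc = None, -np.inf
    for s in shifts:
        src, dst = _overlap_slices(a.shape, s)
        x = a[src].ravel()
        y = b[dst].ravel()
        if x.size < 8:
            continue
        x = x - x.mean()
        y = y - y.mean()
        nx = np.sqrt(x @ x)
        ny = np.sqrt(y @ y)
        if nx == 0.0 or ny == 0.0:
            continue
        ncc = float((x @ y) / (nx * ny))
        if ncc > best_ncc + 1e-12:
            best, best_ncc = s, ncc
    if best is None:
        raise RegistrationError("no valid overlap found within the search radius")
    logger.info("register_translation: shift=%s ncc=%.6f", best, best_ncc)
    return RigidTransform(translation_voxels=tuple(int(v) for v in best))


def apply_transform(volume: ImageVolume, transform: RigidTransform) -> ImageVolume:
    return ImageVolume(shift_integer(volume.values, transform.translation_voxels),
                       volume.voxel_spacing_mm, volume.modality)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _drop_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1 or not mask.any():
        return mask
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    return np.isin(lab, keep)


def segment_iph(t2star: ImageVolume, flair: ImageVolume, brain: RoiMask,
                k: float = 2.0, min_component_cc: float = 0.1,
                refine_with_flair: bool = True) -> RoiMask:
    """Clot segmentation on T2*/SWI with FLAIR border refinement.

    The clot candidate is the largest 26-connected component below
    ``brain median - k * robust SD`` of T2* within the brain.  Because
    susceptibility makes the clot appear ~20% too large, the candidate is
    then trimmed on FLAIR: marginal voxels whose FLAIR signal is closer
    to the surrounding (edema) level than to the clot core level are
    removed.  An empty result is flagged, not raised.
    """
    check_same_grid(t2star, flair)
    check_same_grid(t2star, brain)
    bm = brain.values
    vals = t2star.values[bm]
    med = float(np.median(vals))
    rsd = robust_sd(vals)
    if rsd == 0.0:
        logger.info("segment_iph: uniform T2*, empty mask")
        return RoiMask(np.zeros(t2star.shape, bool), t2star.voxel_spacing_mm,
                       "IPH", flags=("empty", "uniform_t2star"))
    thr = med - k * rsd
    logger.info("segment_iph: t2star threshold=%.3f (median=%.3f, robust_sd=%.3f, k=%.2f)",
                thr, med, rsd, k)
    cand = _largest_component((t2star.values < thr) & bm)
    voxel_cc = t2star.voxel_volume_mm3 / 1000.0
    if cand.sum() * voxel_cc < min_component_cc:
        return RoiMask(np.zeros(t2star.shape, bool), t2star.voxel_spacing_mm,
                       "IPH", flags=("empty", "below_min_size"))

    if refine_with_flair:
        core = ndimage.binary_erosion(cand, structure=_STRUCT26, iterations=2)
        if not core.any():
            core = cand
        clot_ref = float(np.median(flair.values[core]))
        ring = ndimage.binary_dilation(cand, structure=_STRUCT26) & ~cand & bm
        if ring.any():
            margin_ref = float(np.median(flair.values[ring]))
            noise = max(robust_sd(flair.values[core]), 1e-9)
            if abs(margin_ref - clot_ref) > 3.0 * noise:
                logger.info("segment_iph: FLAIR refinement clot_ref=%.3f "
                            "margin_ref=%.3f noise=%.3f", clot_ref, margin_ref, noise)
                keep = np.abs(flair.values - clot_ref) <= np.abs(flair.values - margin_ref)
                cand = _largest_component(cand & keep)
                cand = ndimage.binary_fill_holes(cand)
    return RoiMask(cand, t2star.voxel_spacing_mm, "IPH")


def segment_lesion(flair: ImageVolume, iph: RoiMask, brain: RoiMask,
                   k: float = 2.0, min_component_cc: float = 0.1) -> RoiMask:
    """Whole lesion (clot + edema) on FLAIR, united with the IPH mask.

    FLAIR-hyperintense components (above brain median + k * robust SD)
    that touch the IPH mask are united with it; components smaller than
    ``min_component_cc`` are treated as noise.  With no adjacent
    hyperintensity the lesion equals the IPH mask (flagged: no edema).
    """
    check_same_grid(flair, iph)
    bm = brain.values
    vals = flair.values[bm]
    med = float(np.median(vals))
    rsd = robust_sd(vals)
    thr = med + k * rsd
    logger.info("segment_lesion: flair threshold=%.3f (median=%.3f, robust_sd=%.3f, k=%.2f)",
                thr, med, rsd, k)
    # edema is sought outside the clot: clot voxels are already in the mask
    hyper = (flair.values > thr) & bm & ~iph.values
    min_vox = int(np.ceil(min_component_cc * 1000.0 / flair.voxel_volume_mm3))
    hyper = _drop_small_components(hyper, min_vox)
    lab, n = ndimage.label(hyper, structure=_STRUCT26)
    touch = ndimage.binary_dilation(iph.values, structure=_STRUCT26)
    ids = np.unique(lab[touch & (lab > 0)])
    lesion = iph.values | np.isin(lab, ids[ids > 0])
    flags: tuple[str, ...] = ()
    if lesion.sum() == iph.values.sum():
        flags = ("no_edema",)
    return RoiMask(lesion, flair.voxel_spacing_mm, "LESION", flags=flags)


def derive_phe(lesion: RoiMask, iph: RoiMask) -> RoiMask:
    """PHE = lesion minus IPH (set difference)."""
    check_same_grid(lesion, iph)
    if (iph.values & ~lesion.values).any():
        raise ContractError("IPH mask is not contained in the lesion mask")
    return RoiMask(lesion.values & ~iph.values, lesion.voxel_spacing_mm, "PHE")


def mirror_region(lesion: RoiMask, brain: RoiMask,
                  lesion_dilate_voxels: int = 2,
                  min_voxels: int = 50) -> RoiMask:
    """Lesion reflected across the midsagittal plane, auto-adjusted.

    Reflection maps index i to N-1-i on the first (left-right) axis.
    Reflected voxels falling outside the brain or inside the dilated
    lesion are excluded; fewer than ``min_voxels`` survivors raise
    :class:`MirrorError`.
    """
    check_same_grid(lesion, brain)
    reflected = lesion.values[::-1, :, :]
    excl = ndimage.binary_dilation(lesion.values, structure=_STRUCT26,
                                   iterations=lesion_dilate_voxels)
    mirror = reflected & brain.values & ~excl
    n = int(mirror.sum())
    logger.info("mirror_region: %d voxels survive exclusion", n)
    if n < min_voxels:
        raise MirrorError(f"only {n} mirror voxels survive (minimum {min_voxels})")
    return RoiMask(mirror, lesion.voxel_spacing_mm, "MIRROR")


def compute_mirror_stats(adc: ImageVolume, b1000: ImageVolume,
                         mirror: RoiMask) -> MirrorStats:
    """Median and sample SD of ADC and b1000 over the mirror voxels."""
    check_same_grid(adc, mirror)
    check_same_grid(b1000, mirror)
    if mirror.is_empty():
        raise MirrorError("mirror region is empty")
    a = adc.values[mirror.values].astype(np.float64)
    b = b1000.values[mirror.values].astype(np.float64)
    ddof = 1 if a.size > 1 else 0
    return MirrorStats(
        adc_median=float(np.median(a)),
        adc_sd=float(a.std(ddof=ddof)),
        b1000_median=float(np.median(b)),
        b1000_sd=float(b.std(ddof=ddof)),
        n_voxels=int(a.size),
    )


def detect_pdr(adc: ImageVolume, b1000: ImageVolume, phe: RoiMask,
               mirror_stats: MirrorStats,
               exclude: RoiMask | None = None,
               adc_sd_factor: float = 1.5,
               b1000_sd_factor: float = 1.5,
               shell_voxels: int = 1,
               min_component_cc: float = 0.05,
               search_region: str = "phe_plus_shell") -> RoiMask:
    """Mirror-thresholded rim detection.

    Candidate voxels are the PHE plus a thin shell outside its border
    (configurable: "phe_plus_shell", "phe_only" or "shell_only"), minus
    the ``exclude`` mask (the IPH, so the rim can never enter the clot).
    A voxel is rim if ADC <= mirror median - adc_sd_factor * mirror SD
    AND b1000 >= mirror median + b1000_sd_factor * mirror SD.  Connected
    components smaller than ``min_component_cc`` are discarded.  An empty
    mask is a valid outcome.
    """
    check_same_grid(adc, phe)
    if adc_sd_factor < 0 or b1000_sd_factor < 0:
        raise ParameterError("SD factors must be non-negative")
    pm = phe.values
    grown = ndimage.binary_dilation(pm, structure=_STRUCT26,
                                    iterations=max(int(shell_voxels), 0)) \
        if shell_voxels > 0 else pm
    if search_region == "phe_plus_shell":
        cand = grown
    elif search_region == "phe_only":
        cand = pm
    elif search_region == "shell_only":
        cand = grown & ~pm
    else:
        raise ParameterError(f"unknown search_region {search_region!r}")
    if exclude is not None:
        cand = cand & ~exclude.values

    adc_cut = mirror_stats.adc_median - adc_sd_factor * mirror_stats.adc_sd
    b_cut = mirror_stats.b1000_median + b1000_sd_factor * mirror_stats.b1000_sd
    logger.info("detect_pdr: adc_cutoff=%.3f (median=%.3f, sd=%.3f, f=%.2f) "
                "b1000_cutoff=%.3f (median=%.3f, sd=%.3f, f=%.2f)",
                adc_cut, mirror_stats.adc_median, mirror_stats.adc_sd,
                adc_sd_factor, b_cut, mirror_stats.b1000_median,
                mirror_stats.b1000_sd, b1000_sd_factor)
    sel = cand & (adc.values <= adc_cut) & (b1000.values >= b_cut)
    min_vox = int(np.ceil(min_component_cc * 1000.0 / adc.voxel_volume_mm3))
    sel = _drop_small_components(sel, min_vox)
    return RoiMask(sel, adc.voxel_spacing_mm, "PDR")


def classify_pdr_status(pdr: RoiMask,
                        min_positive_cc: float = 0.1) -> tuple[bool, float]:
    """PDR positivity call: positive iff rim volume >= the cutoff (in cc)."""
    vol = pdr.volume_cc
    return vol >= min_positive_cc, vol


@dataclass
class SegmentationParams:
    """All tunable knobs of the automated ROI procedure."""

    t2star_k: float = 2.0
    flair_k: float = 2.0
    refine_with_flair: bool = True
    min_iph_component_cc: float = 0.1
    adc_sd_factor: float = 1.5
    b1000_sd_factor: float = 1.5
    shell_voxels: int = 1
    min_pdr_component_cc: float = 0.05
    min_positive_cc: float = 0.1
    search_region: str = "phe_plus_shell"
    mirror_dilate_voxels: int = 2
    mirror_min_voxels: int = 50
    register: bool = False
    registration_radius_voxels: int = 3

    def __post_init__(self) -> None:
        for name in ("t2star_k", "flair_k", "adc_sd_factor", "b1000_sd_factor"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass
class CaseSegmentation:
    """Masks, mirror statistics and the positivity call for one case."""

    iph: RoiMask
    lesion: RoiMask
    phe: RoiMask
    mirror: RoiMask
    pdr: RoiMask
    mirror_stats: MirrorStats
    pdr_positive: bool
    pdr_volume_cc: float
    transforms: dict[str, RigidTransform]


def segment_case(volumes: dict[str, ImageVolume], brain: RoiMask,
                 params: SegmentationParams | None = None) -> CaseSegmentation:
    """Run the full ROI procedure on one co-registered (or registerable) case."""
    p = params or SegmentationParams()
    vols = dict(volumes)
    transforms: dict[str, RigidTransform] = {}
    if p.register:
        fixed = vols["ADC"]
        for mod in ("FLAIR", "B1000", "T2STAR"):
            t = register_translation(vols[mod], fixed,
                                     p.registration_radius_voxels)
            transforms[mod] = t
            vols[mod] = apply_transform(vols[mod], t)

    iph = segment_iph(vols["T2STAR"], vols["FLAIR"], brain,
                      k=p.t2star_k, min_component_cc=p.min_iph_component_cc,
                      refine_with_flair=p.refine_with_flair)
    lesion = segment_lesion(vols["FLAIR"], iph, brain, k=p.flair_k)
    phe = derive_phe(lesion, iph)
    mirror = mirror_region(lesion, brain,
                           lesion_dilate_voxels=p.mirror_dilate_voxels,
                           min_voxels=p.mirror_min_voxels)
    mstats = compute_mirror_stats(vols["ADC"], vols["B1000"], mirror)
    pdr = detect_pdr(vols["ADC"], vols["B1000"], phe, mstats, exclude=iph,
                     adc_sd_factor=p.adc_sd_factor,
                     b1000_sd_factor=p.b1000_sd_factor,
                     shell_voxels=p.shell_voxels,
                     min_component_cc=p.min_pdr_component_cc,
                     search_region=p.search_region)
    positive, vol = classify_pdr_status(pdr, p.min_positive_cc)
    return CaseSegmentation(iph=iph, lesion=lesion, phe=phe, mirror=mirror,
                            pdr=pdr, mirror_stats=mstats, pdr_positive=positive,
                            pdr_volume_cc=vol, transforms=transforms)
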