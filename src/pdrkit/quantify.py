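"""Per-case measurements: ROI volumes in cc, ADC order statistics, and
relative ADC (rADC) against the contralateral mirror region.

Quantiles use linear interpolation between order statistics; rADC is the
ROI's median ADC divided by the mirror median and is reported as a
fraction (percent only at the presentation layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import CaseSegmentation, MirrorStats
from .volumes import ImageVolume, ParameterError, RoiMask, check_same_grid


@dataclass(frozen=True)
class RoiStats:
    """Quartiles, mean and volume of one ROI (ADC in 1e-6 mm^2/s)."""

    p25: float
    mean: float
    median: float
    p75: float
    volume_cc: float
    n_voxels: int


@dataclass
class LesionQuant:
    """All per-case measurements; PDR entries are None when PDR-negative."""

    iph: RoiStats
    phe: RoiStats | None
    pdr: RoiStats | None
    radc_iph: float
    radc_phe: float          # NaN when PHE empty
    radc_pdr: float          # NaN when PDR absent
    mirror_stats: MirrorStats
    pdr_positive: bool


def roi_volume_cc(mask: RoiMask) -> float:
    """Voxel count times physical voxel volume, in cc."""
    return mask.volume_cc


def roi_adc_stats(adc: ImageVolume, mask: RoiMask) -> RoiStats:
    """P25 / mean / median / P75 of ADC over a non-empty ROI, plus volume."""
    check_same_grid(adc, mask)
    if mask.is_empty():
        raise ParameterError("cannot compute ROI statistics of an empty mask")
    v = adc.values[mask.values].astype(np.float64)
    p25, med, p75 = np.percentile(v, [25.0, 50.0, 75.0])
    return RoiStats(p25=float(p25), mean=float(v.mean()), median=float(med),
                    p75=float(p75), volume_cc=mask.volume_cc, n_voxels=v.size)


def relative_adc(roi_median: float, mirror_median: float) -> float:
    """rADC = ROI median ADC / mirror median ADC."""
    if mirror_median <= 0:
        raise ParameterError("mirror median must be positive")
    return float(roi_median) / float(mirror_median)


def quantify_case(volumes: dict[str, ImageVolume], seg: CaseSegmentation,
                  exclude_pdr_from_phe: bool = True) -> LesionQuant:
    """Assemble all per-case measurements from a segmentation result.

    When the detected rim lies inside the PHE, its voxels are by default
    excluded from the PHE statistics so the two compartments do not mix
    (configurable; an explicitly stated assumption of this pipeline).
    """
    adc = volumes["ADC"]
    if seg.iph.is_empty():
        raise ParameterError("cannot quantify a case with an empty IPH mask")
    iph_stats = roi_adc_stats(adc, seg.iph)

    phe_mask = seg.phe.values
    if exclude_pdr_from_phe and not seg.pdr.is_empty():
        phe_mask = phe_mask & ~seg.pdr.values
    phe_roi = RoiMask(phe_mask, seg.phe.voxel_spacing_mm, "PHE")
    phe_stats = roi_adc_stats(adc, phe_roi) if not phe_roi.is_empty() else None

    pdr_stats = roi_adc_stats(adc, seg.pdr) if seg.pdr_positive else None

    mm = seg.mirror_stats.adc_median
    return LesionQuant(
        iph=iph_stats,
        phe=phe_stats,
        pdr=pdr_stats,
        radc_iph=relative_adc(iph_stats.median, mm),
        radc_phe=relative_adc(phe_stats.median, mm) if phe_stats else math.nan,
        radc_pdr=relative_adc(pdr_stats.median, mm) if pdr_stats else math.nan,
        mirror_stats=seg.mirror_stats,
        pdr_positive=seg.pdr_positive,
    )


def quant_to_row(case_id: str, quant: LesionQuant) -> dict:
    """Flatten a LesionQuant into one cohort-CSV row."""
    def unpack(prefix: str, s: RoiStats | None) -> dict:
        if s is None:
            return {f"{prefix}_{k}": (0.0 if k in ("volume_cc", "n_voxels") else math.nan)
                    for k in ("p25", "mean", "median", "p75", "volume_cc", "n_voxels")}
        return {f"{prefix}_p25": s.p25, f"{prefix}_mean": s.mean,
                f"{prefix}_median": s.median, f"{prefix}_p75": s.p75,
                f"{prefix}_volume_cc": s.volume_cc, f"{prefix}_n_voxels": s.n_voxels}

    row = {"id": case_id}
    row.update(unpack("iph", quant.iph))
    row.update(unpack("phe", quant.phe))
    row.update(unpack("pdr", quant.pdr))
    row.update({
        "radc_iph": quant.radc_iph,
        "radc_phe": quant.radc_phe,
        "radc_pdr": quant.radc_pdr,
        "mirror_adc_median": quant.mirror_stats.adc_median,
        "mirror_adc_sd": quant.mirror_stats.adc_sd,
        "pdr_positive": quant.pdr_positive,
    })
    return row
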