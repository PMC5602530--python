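"""End-to-end pipeline: simulate -> segment -> quantify -> cohort stats.

Everything is seeded; re-running with the same config reproduces
byte-identical outputs (NIfTI volumes and masks, per-case JSON reports,
the imaging CSV, the cohort CSV, the stats report and the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, cohort_to_dataframe, make_cohort
from .io import write_cohort, write_mask, write_truth, write_volume
from .phantom import (
    PhantomSpec,
    TruthLabels,
    brain_mask_for,
    make_phantom,
    spec_from_dict,
    spec_to_dict,
)
from .quantify import quant_to_row, quantify_case
from .segmentation import SegmentationParams, segment_case
from .stats import analyze_cohort
from .volumes import ParameterError, RoiMask

_SEED_CAP = 2 ** 31 - 1


@dataclass
class PipelineConfig:
    """Seed, study size and every tunable threshold of one run.

    Round-trips losslessly through JSON (`to_json` / `from_json`).
    """

    seed: int
    n_cases: int = 10
    pdr_prevalence: float = 56 / 83
    cohort_n_patients: int = 83
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    quantile_convention: str = "linear"
    exclude_pdr_from_phe: bool = True
    write_images: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("a seed is mandatory (no wall-clock seeding)")
        if self.n_cases < 0 or self.cohort_n_patients < 0:
            raise ParameterError("case counts must be non-negative")
        if not (0.0 <= self.pdr_prevalence <= 1.0):
            raise ParameterError("prevalence must lie in [0, 1]")
        if self.quantile_convention != "linear":
            raise ParameterError("only the 'linear' quantile convention is supported")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = spec_to_dict(self.phantom)
        d["segmentation"] = dataclasses.asdict(self.segmentation)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["phantom"] = spec_from_dict(d["phantom"])
        d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def _case_report(seg, quant) -> dict:
    return {
        "pdr_positive": bool(seg.pdr_positive),
        "pdr_volume_cc": float(seg.pdr_volume_cc),
        "mirror_stats": dataclasses.asdict(seg.mirror_stats),
        "mask_flags": {"iph": list(seg.iph.flags), "lesion": list(seg.lesion.flags)},
        "quantification": quant_to_row("", quant),
    }


def run_case(spec: PhantomSpec, seed: int, params: SegmentationParams,
             exclude_pdr_from_phe: bool = True):
    """Simulate, segment and quantify one phantom case."""
    case = make_phantom(spec, seed)
    brain = RoiMask(brain_mask_for(spec), spec.voxel_spacing_mm, "BRAIN")
    seg = segment_case(case.volumes, brain, params)
    quant = quantify_case(case.volumes, seg,
                          exclude_pdr_from_phe=exclude_pdr_from_phe)
    return case, seg, quant


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages and write every artifact plus a manifest.

    Per-case failures are isolated and summarised in the manifest; the
    caller decides the exit status from ``manifest["failures"]``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    case_seeds = rng.integers(0, _SEED_CAP, size=config.n_cases)
    rim_flags = rng.random(config.n_cases) < config.pdr_prevalence
    cohort_seed = int(rng.integers(0, _SEED_CAP))

    outputs: list[str] = []
    failures: dict[str, str] = {}
    rows = []
    for i in range(config.n_cases):
        case_id = f"case_{i:04d}"
        spec = dataclasses.replace(config.phantom, pdr_present=bool(rim_flags[i]))
        try:
            case, seg, quant = run_case(spec, int(case_seeds[i]),
                                        config.segmentation,
                                        config.exclude_pdr_from_phe)
        except Exception as exc:  # noqa: BLE001 - isolate per-case failures
            failures[case_id] = f"{type(exc).__name__}: {exc}"
            continue
        case_dir = out / case_id
        case_dir.mkdir(exist_ok=True)
        if config.write_images:
            for mod, vol in case.volumes.items():
                p = write_volume(vol, case_dir / f"{mod.lower()}.nii")
                outputs.append(str(p.relative_to(out)))
            outputs.append(str(write_truth(case.truth, case_dir / "truth.nii")
                               .relative_to(out)))
            for name, mask in (("iph", seg.iph), ("lesion", seg.lesion),
                               ("phe", seg.phe), ("mirror", seg.mirror),
                               ("pdr", seg.pdr)):
                p = write_mask(mask, case_dir / f"mask_{name}.nii")
                outputs.append(str(p.relative_to(out)))
        report = _case_report(seg, quant)
        report["quantification"]["id"] = case_id
        report["seed"] = int(case_seeds[i])
        report["pdr_present_truth"] = bool(rim_flags[i])
        _dump_json(report, case_dir / "report.json")
        outputs.append(f"{case_id}/report.json")
        row = quant_to_row(case_id, quant)
        row["pdr_present_truth"] = bool(rim_flags[i])
        rows.append(row)

    imaging_df = pd.DataFrame(rows)
    imaging_csv = out / "imaging_quantification.csv"
    imaging_df.to_csv(imaging_csv, index=False, float_format="%.10g")
    outputs.append(imaging_csv.name)

    cohort = make_cohort(CohortSpec(n_patients=config.cohort_n_patients,
                                    pdr_prevalence=config.pdr_prevalence),
                         cohort_seed)
    cohort_df = cohort_to_dataframe(cohort)
    outputs.append(write_cohort(cohort_df, out / "cohort.csv").name)
    stats_report = analyze_cohort(cohort_df)
    _dump_json(stats_report, out / "stats_report.json")
    outputs.append("stats_report.json")

    config_text = config.to_json()
    manifest = {
        "pdrkit_version": __version__,
        "seed": int(config.seed),
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "n_cases": config.n_cases,
        "cases": [f"case_{i:04d}" for i in range(config.n_cases)
                  if f"case_{i:04d}" not in failures],
        "failures": failures,
        "outputs": sorted(outputs + ["manifest.json"]),
    }
    _dump_json(manifest, out / "manifest.json")
    return manifest
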