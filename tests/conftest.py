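"""Shared fixtures: phantom cases are expensive enough to build once per
session and reuse across test modules."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from pdrkit.phantom import PhantomSpec, build_geometry
from pdrkit.pipeline import run_case
from pdrkit.segmentation import SegmentationParams


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return build_geometry(default_spec)


@pytest.fixture(scope="session")
def default_case(default_spec):
    """One fully processed default phantom (rim present), seed 42."""
    case, seg, quant = run_case(default_spec, 42, SegmentationParams())
    return case, seg, quant


@pytest.fixture(scope="session")
def norim_case():
    spec = PhantomSpec(pdr_present=False)
    case, seg, quant = run_case(spec, 43, SegmentationParams())
    return case, seg, quant


@pytest.fixture(scope="session")
def detection_batch():
    """50 processed phantoms, half with a rim, fixed seeds.

    Returns a list of (rim_truth, case, seg, quant).
    """
    rng = np.random.default_rng(20170918)
    seeds = rng.integers(0, 2 ** 31 - 1, size=50)
    out = []
    params = SegmentationParams()
    for i, seed in enumerate(seeds):
        rim = i % 2 == 0
        spec = dataclasses.replace(PhantomSpec(), pdr_present=rim)
        case, seg, quant = run_case(spec, int(seed), params)
        out.append((rim, case, seg, quant))
    return out


@pytest.fixture(scope="session")
def rim_batch(detection_batch):
    """The 25 rim-positive phantoms of the detection batch."""
    return [item for item in detection_batch if item[0]]
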