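"""Shared fixtures: one moderate synthetic scene (and its processed
outputs) reused across the suite to keep runtime down."""

from __future__ import annotations

import numpy as np
import pytest

from pnnquant.classify import classify_all
from pnnquant.detection import detect_and_segment
from pnnquant.quantify import measure_all
from pnnquant.synthetic import GeneratorConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """512x512 scene, 14 cells, mixed phenotypes, default noise."""
    cfg = GeneratorConfig(image_shape=(512, 512), n_cells=14, seed=11)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def processed_scene(small_scene):
    stack, gt = small_scene
    objects, nuclei, log = detect_and_segment(stack)
    records = measure_all(stack, objects)
    phenotypes = classify_all(stack, objects, nuclei, records)
    return {
        "stack": stack,
        "truth": gt,
        "objects": objects,
        "nuclei": nuclei,
        "records": records,
        "phenotypes": phenotypes,
        "log": log,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def match_truth(obj, cells):
    """Nearest true cell to a detected object, by centre distance."""
    return min(
        cells,
        key=lambda c: np.hypot(obj.center[0] - c.center[0], obj.center[1] - c.center[1]),
    )
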