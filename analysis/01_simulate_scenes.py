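#!/usr/bin/env python
"""Render reference synthetic scenes and their ground-truth tables.

Writes one tissue-style scene (mixed phenotypes, rank coupling 0.816)
and a control / treated culture pair under results/scenes/, as
multipage TIFFs with JSON sidecars plus truth CSVs.  These are the
inputs the later drivers re-analyse from disk, exercising the same
read path a real acquisition would take.
"""

import dataclasses
from pathlib import Path

from pnnquant import GeneratorConfig, culture_config, generate_scene, write_ground_truth
from pnnquant.io import write_stack

OUT = Path(__file__).resolve().parents[1] / "results" / "scenes"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    jobs = {
        "invivo": GeneratorConfig(n_cells=40, seed=101),
        "culture_control": culture_config(n_cells=30, exact_count=True, seed=111),
        "culture_treated": culture_config(treated=True, n_cells=30, exact_count=True, seed=112),
    }
    for name, cfg in jobs.items():
        stack, truth = generate_scene(cfg)
        write_stack(stack, OUT / f"{name}.tif")
        write_ground_truth(truth, OUT / f"{name}_truth.csv")
        n_pnn = len(truth.pnn_cells)
        print(f"{name}: {len(truth.cells)} cells, {n_pnn} with a PNN -> {OUT / name}.tif")


if __name__ == "__main__":
    main()
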