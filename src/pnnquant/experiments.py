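"""Parameter-recovery experiments on synthetic scenes.

The published numbers these experiments shadow come from microscopy
data that was never deposited, so the check is recovery: generate
scenes whose ground truth is set to the reported value, run the full
pipeline, and compare what comes back.  Problem sizes (number of
images, cells per image) are chosen so each experiment holds several
hundred to a thousand nets while staying desk-scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .classify import classify_all, census
from .detection import DetectionParams, detect_and_segment
from .pipeline import PipelineConfig, process_stack, simulate_stacks
from .quantify import colocalize, measure_all
from .synthetic import GeneratorConfig, culture_config
from .culture import enzyme_reduction_analysis

__all__ = [
    "coloc_recovery",
    "census_recovery",
    "detection_quality",
    "ttest_calibration",
    "enzyme_direction",
]

IN_VIVO_RHO = 0.816  # reported tissue colocalization coefficient
SURFACE_PERCENT = 66.0  # reported % of PNN cells with tag on the net
INTRACELLULAR_PERCENT = 29.0  # reported % with vesicular tag puncta


def coloc_recovery(
    seed: int,
    coupling_rho: float = IN_VIVO_RHO,
    n_images: int = 7,
    n_cells: int = 80,
    image_shape: tuple[int, int] = (1024, 1024),
) -> dict:
    """Full-pipeline Spearman recovery.

    Scenes hold ``n_images * n_cells`` PNN-bearing, surface-positive
    cells (560 by default) whose ring intensities are rank-coupled at
    ``coupling_rho``; the pipeline detects, gates, segments, measures
    both channels over the same masks and pools the Spearman
    correlation.
    """
    gen = GeneratorConfig(
        image_shape=image_shape, n_cells=n_cells,
        frac_pnn=1.0, frac_surface_positive=1.0,
        coupling_rho=coupling_rho, exact_count=True,
    )
    config = PipelineConfig(generator=gen, n_images=n_images, seed=seed)
    records = []
    n_true = 0
    for i, (stack, gt) in enumerate(simulate_stacks(gen, n_images, seed)):
        res = process_stack(stack, config, image_id=f"sim_{i:03d}", classify=False)
        records.extend(res.records)
        n_true += len(gt.pnn_cells)
    result = colocalize(records)
    return {
        "rho": result.rho,
        "n_detected": result.n,
        "n_true": n_true,
        "coupling_rho": coupling_rho,
    }


def census_recovery(
    seed: int,
    surface_percent: float = SURFACE_PERCENT,
    intracellular_percent: float = INTRACELLULAR_PERCENT,
    n_images: int = 13,
    n_cells: int = 80,
    image_shape: tuple[int, int] = (1024, 1024),
) -> dict:
    """Phenotype-census recovery on exact-count scenes.

    1040 PNN-positive cells by default, with exactly the configured
    fractions surface-positive and intracellular-punctate; the census
    is taken over the detected PNN population at default thresholds.
    """
    gen = GeneratorConfig(
        image_shape=image_shape, n_cells=n_cells,
        frac_pnn=1.0,
        frac_surface_positive=surface_percent / 100.0,
        frac_intracellular=intracellular_percent / 100.0,
        exact_count=True,
    )
    config = PipelineConfig(generator=gen, n_images=n_images, seed=seed)
    phen = []
    truth_surf = truth_intra = n_true = 0
    for i, (stack, gt) in enumerate(simulate_stacks(gen, n_images, seed)):
        res = process_stack(stack, config, image_id=f"sim_{i:03d}")
        phen.extend(res.phenotypes)
        truth_surf += sum(c.surface_positive for c in gt.pnn_cells)
        truth_intra += sum(c.intracellular_punctate for c in gt.pnn_cells)
        n_true += len(gt.pnn_cells)
    pop = census(phen)
    return {
        "surface_percent": pop.frac_surface_positive,
        "intracellular_percent": pop.frac_intracellular,
        "n_detected": pop.n_pnn_cells,
        "n_true": n_true,
        "truth_surface_percent": 100.0 * truth_surf / n_true,
        "truth_intracellular_percent": 100.0 * truth_intra / n_true,
    }


def _match_objects(objects, truth_cells, tol_center: float = 3.0, tol_radius: float = 3.0):
    """Greedy 1:1 matching of detections to true PNN cells."""
    unmatched = {c.cell_id: c for c in truth_cells}
    pairs = []
    for obj in sorted(objects, key=lambda o: -o.detection_score):
        best, best_d = None, np.inf
        for cid, cell in unmatched.items():
            d = np.hypot(obj.center[0] - cell.center[0], obj.center[1] - cell.center[1])
            if d < best_d:
                best, best_d = cid, d
        if (
            best is not None
            and best_d <= tol_center
            and abs(obj.radius - unmatched[best].pnn_radius) <= tol_radius
        ):
            pairs.append((obj, unmatched.pop(best)))
    return pairs


def detection_quality(
    seeds: range | list[int],
    n_cells: int = 12,
    image_shape: tuple[int, int] = (512, 512),
    frac_pnn: float = 0.7,
) -> dict:
    """Recall and precision of ring detection vs ground truth over a
    set of seeds (matching tolerance: 3 px centre, 3 px radius)."""
    tp = fp = fn = 0
    for seed in seeds:
        gen = GeneratorConfig(
            image_shape=image_shape, n_cells=n_cells,
            frac_pnn=frac_pnn, exact_count=True, seed=int(seed),
        )
        from .synthetic import generate_scene

        stack, gt = generate_scene(gen)
        objects, _, _ = detect_and_segment(stack)
        pairs = _match_objects(objects, gt.pnn_cells)
        tp += len(pairs)
        fp += len(objects) - len(pairs)
        fn += len(gt.pnn_cells) - len(pairs)
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    return {"recall": recall, "precision": precision, "tp": tp, "fp": fp, "fn": fn}


def ttest_calibration(
    seed: int,
    n_replicates: int = 5000,
    n_per_group: int = 20,
    alpha: float = 0.05,
    shift_sd: float = 1.0,
) -> dict:
    """Type-I error and power of the pooled-variance two-sample t.

    Null replicates draw both groups from N(0,1); power replicates
    shift the second group by ``shift_sd`` SDs and are compared with
    the noncentral-t closed form.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_replicates, n_per_group))
    b = rng.standard_normal((n_replicates, n_per_group))
    _, p_null = stats.ttest_ind(a, b, axis=1, equal_var=True)
    type1 = float(np.mean(p_null < alpha))

    b_shift = rng.standard_normal((n_replicates, n_per_group)) + shift_sd
    a2 = rng.standard_normal((n_replicates, n_per_group))
    _, p_alt = stats.ttest_ind(a2, b_shift, axis=1, equal_var=True)
    power = float(np.mean(p_alt < alpha))

    df = 2 * n_per_group - 2
    nc = shift_sd * np.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power_theory = float(
        stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )
    return {
        "type1": type1,
        "power": power,
        "power_theory": power_theory,
        "alpha": alpha,
        "n_replicates": n_replicates,
    }


def enzyme_direction(
    seed: int,
    intensity_scale: float = 0.3,
    n_per_group: int = 20,
    image_shape: tuple[int, int] = (768, 768),
    scale_channels: tuple[str, ...] = ("wfa", "comparison"),
) -> dict:
    """One enzyme-treatment simulation: ring intensities scaled down by
    ``intensity_scale`` in the chosen channels of the treated scene,
    ~``n_per_group`` nets per condition, per-channel relative-intensity
    t-tests."""
    def records_for(scale_wfa: float, scale_cmp: float, s: int):
        gen = GeneratorConfig(
            image_shape=image_shape, n_cells=n_per_group,
            frac_pnn=1.0, frac_surface_positive=1.0, frac_intracellular=0.0,
            exact_count=True, seed=s,
        )
        lo, hi = gen.intensity.wfa_range
        gen.intensity.wfa_range = (lo * scale_wfa, hi * scale_wfa)
        lo, hi = gen.intensity.comparison_range
        gen.intensity.comparison_range = (lo * scale_cmp, hi * scale_cmp)
        from .synthetic import generate_scene

        stack, _ = generate_scene(gen)
        objects, _, _ = detect_and_segment(stack)
        return measure_all(stack, objects)

    s_wfa = intensity_scale if "wfa" in scale_channels else 1.0
    s_cmp = intensity_scale if "comparison" in scale_channels else 1.0
    ctrl = records_for(1.0, 1.0, seed)
    trt = records_for(s_wfa, s_cmp, seed + 50_000)
    results = enzyme_reduction_analysis(ctrl, trt)
    return {
        ch: {
            "p_value": r.p_value,
            "direction": r.effect_direction,
            "group_means": r.group_means,
            "group_ns": r.group_ns,
        }
        for ch, r in results.items()
    }
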