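"""End-to-end runs: simulate or load images, detect, measure, classify,
and write the report tables.

Two entry points mirror the two experimental designs:

``run_coloc``
    The tissue-section workflow — detect rings, gate on nuclei, segment,
    measure both channels over the same region, phenotype each cell,
    and report the pooled Spearman colocalization plus the census.
``run_culture``
    The dish workflow — per-condition PNN density (per 50 mm²), per-PNN
    size and WFA intensity (absolute and relative to the control
    condition), PV-gated PNN fractions, and the group comparisons.

Every run writes a log with all parameters, the seed and per-stage
object counts; identical (config, seed) reproduce reports byte for
byte (no timestamps enter any output).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import culture as cult
from .classify import CellPhenotype, ClassifyParams, census, classify_all
from .detection import DetectionParams, detect_and_segment
from .io import ImageStack, read_stack, write_measurements
from .quantify import MeasurementRecord, colocalize
from .synthetic import GeneratorConfig, GroundTruth, generate_scene

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "StageResult",
    "simulate_stacks",
    "process_stack",
    "run_coloc",
    "run_culture",
]


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and the input."""


@dataclass
class PipelineConfig:
    pixel_size: float = 0.5
    channel_map: dict[int, str] | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    channel_a: str = "wfa"
    channel_b: str = "comparison"
    generator: GeneratorConfig | None = None
    n_images: int = 1
    seed: int = 0


@dataclass
class StageResult:
    """Everything one image contributes to a report."""

    image_id: str
    objects: list
    nuclei: list
    records: list[MeasurementRecord]
    phenotypes: list[CellPhenotype]
    log: dict


def simulate_stacks(
    generator: GeneratorConfig, n_images: int, base_seed: int
) -> list[tuple[ImageStack, GroundTruth]]:
    """Render ``n_images`` scenes with per-image seeds base_seed + i."""
    out = []
    for i in range(n_images):
        cfg = dataclasses.replace(generator, seed=int(base_seed) + i)
        out.append(generate_scene(cfg))
    return out


def process_stack(
    stack: ImageStack,
    config: PipelineConfig,
    image_id: str = "",
    subject_id: str = "",
    classify: bool = True,
) -> StageResult:
    """Run detection, measurement and (optionally) phenotyping on one
    stack.  Any stage failure is re-raised naming the stage and image."""
    from .quantify import measure_all

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineStageError(
                f"stage {name!r} failed for image {image_id!r}: {exc}"
            ) from exc

    objects, nuclei, log = _stage(
        "detect", lambda: detect_and_segment(stack, config.detection)
    )
    channels = tuple(
        ch for ch in (config.channel_a, config.channel_b) if ch in stack
    )
    records = _stage(
        "measure",
        lambda: measure_all(stack, objects, channels=channels,
                            image_id=image_id, subject_id=subject_id),
    )
    phenotypes: list[CellPhenotype] = []
    if classify and objects and config.channel_b in stack:
        phenotypes = _stage(
            "classify",
            lambda: classify_all(stack, objects, nuclei, records, config.classify,
                                 channel=config.channel_b),
        )
    return StageResult(image_id, objects, nuclei, records, phenotypes, log)


def _load_inputs(
    config: PipelineConfig, inputs
) -> list[tuple[ImageStack, str]]:
    """Inputs are image paths, or None to simulate from the config."""
    if inputs is None:
        if config.generator is None:
            raise ValueError("no inputs given and no generator configured")
        sims = simulate_stacks(config.generator, config.n_images, config.seed)
        return [(stack, f"sim_{i:03d}") for i, (stack, _) in enumerate(sims)]
    out = []
    for p in inputs:
        p = Path(p)
        stack = read_stack(p, channel_map=config.channel_map)
        out.append((stack, p.stem))
    return out


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _phenotype_frame(phenotypes: list[tuple[str, CellPhenotype]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image_id": img,
                "pnn_id": p.pnn_id,
                "surface_positive": p.surface_positive,
                "intracellular_punctate": p.intracellular_punctate,
                "surface_score": p.surface_score,
                "puncta_count": p.puncta_count,
            }
            for img, p in phenotypes
        ],
        columns=[
            "image_id", "pnn_id", "surface_positive",
            "intracellular_punctate", "surface_score", "puncta_count",
        ],
    )


def run_coloc(config: PipelineConfig, inputs=None, out_dir: str | Path | None = None) -> dict:
    """The section workflow over a set of images; returns the report and
    writes measurements.csv, phenotypes.csv, census.json,
    colocalization.json and run_log.json when ``out_dir`` is given."""
    loaded = _load_inputs(config, inputs)
    results = [
        process_stack(stack, config, image_id=image_id) for stack, image_id in loaded
    ]
    all_records = [r for res in results for r in res.records]
    all_phen = [(res.image_id, p) for res in results for p in res.phenotypes]

    if all_phen:
        pop = census([p for _, p in all_phen])
        census_report = dataclasses.asdict(pop)
    else:
        census_report = {"n_pnn_cells": 0, "note": "no objects"}

    if len(all_records) >= 3 and all(
        config.channel_b in r.mean_intensity for r in all_records
    ):
        res = colocalize(all_records, config.channel_a, config.channel_b)
        coloc_report = {
            "rho": res.rho, "n": res.n,
            "channel_pair": list(res.channel_pair), "grouping": res.grouping,
        }
    else:
        coloc_report = {"rho": None, "n": len(all_records), "note": "fewer than 3 records"}

    report = {
        "census": census_report,
        "colocalization": coloc_report,
        "per_image": {res.image_id: res.log for res in results},
        "n_images": len(results),
        "seed": config.seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_measurements(all_records, out_dir / "measurements.csv")
        _phenotype_frame(all_phen).to_csv(out_dir / "phenotypes.csv", index=False)
        _json_dump(census_report, out_dir / "census.json")
        _json_dump(coloc_report, out_dir / "colocalization.json")
        _json_dump(_run_log(config, report), out_dir / "run_log.json")
    return report


def _run_log(config: PipelineConfig, report: dict) -> dict:
    cfg = dataclasses.asdict(config)
    if cfg.get("channel_map"):
        cfg["channel_map"] = {str(k): v for k, v in cfg["channel_map"].items()}
    return {"config": cfg, "stage_counts": report.get("per_image", {}), "seed": config.seed}


def run_culture(
    config: PipelineConfig, manifest: pd.DataFrame | str | Path, out_dir: str | Path | None = None
) -> dict:
    """The dish workflow.

    ``manifest`` maps images to conditions: columns ``image`` (path),
    ``condition`` and ``dish_id``.  The first condition listed is the
    control/reference.  Per-PNN area and WFA intensity are pooled per
    condition and compared relative to the control mean; density and
    PV-PNN fraction are compared per dish.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"image", "condition", "dish_id"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    for p in manifest["image"]:
        if not Path(p).exists():
            raise FileNotFoundError(f"manifest references a missing image: {p}")

    conditions = list(dict.fromkeys(manifest["condition"]))
    counts = manifest["condition"].value_counts()
    for cond in conditions:
        if counts[cond] < 2:
            raise ValueError(
                f"condition {cond!r} has {counts[cond]} observation(s); need >= 2"
            )

    dishes: list[cult.DishSummary] = []
    records_by_cond: dict[str, list[MeasurementRecord]] = {c: [] for c in conditions}
    for row in manifest.itertuples(index=False):
        stack = read_stack(Path(row.image), channel_map=config.channel_map)
        res = process_stack(
            stack, config, image_id=Path(row.image).stem,
            subject_id=str(row.dish_id), classify=False,
        )
        dishes.append(
            cult.summarize_dish(
                stack, res.objects, res.nuclei, res.records,
                dish_id=str(row.dish_id), condition=str(row.condition),
            )
        )
        records_by_cond[str(row.condition)].extend(res.records)

    control = conditions[0]
    ctrl_records = records_by_cond[control]
    dish_df = pd.DataFrame(
        [
            {
                "dish_id": d.dish_id, "condition": d.condition,
                "pnn_count": d.pnn_count, "imaged_area_mm2": d.imaged_area_mm2,
                "density_per_50mm2": d.density_per_50mm2,
                "pv_count": d.pv_count, "pv_with_pnn_count": d.pv_with_pnn_count,
                "pv_pnn_percent": (
                    cult.pv_pnn_fraction(d) if d.pv_count > 0 else np.nan
                ),
            }
            for d in dishes
        ]
    )

    comparisons: dict[str, dict] = {}
    for cond in conditions[1:]:
        per = {}
        a = dish_df[dish_df.condition == control]
        b = dish_df[dish_df.condition == cond]
        per["density"] = dataclasses.asdict(
            cult.compare_groups(a["density_per_50mm2"], b["density_per_50mm2"])
        )
        tbl_a = cult.pnn_size_and_intensity(ctrl_records, ctrl_records)
        tbl_b = cult.pnn_size_and_intensity(records_by_cond[cond], ctrl_records)
        per["area"] = dataclasses.asdict(
            cult.compare_groups(tbl_a["rel_area"], tbl_b["rel_area"])
        )
        per["wfa_intensity"] = dataclasses.asdict(
            cult.compare_groups(tbl_a["rel_wfa"], tbl_b["rel_wfa"])
        )
        if a["pv_count"].gt(0).all() and b["pv_count"].gt(0).all():
            per["pv_pnn_fraction"] = dataclasses.asdict(
                cult.compare_groups(a["pv_pnn_percent"], b["pv_pnn_percent"])
            )
        comparisons[cond] = per

    report = {
        "control": control,
        "conditions": conditions,
        "comparisons": comparisons,
        "n_dishes": int(len(manifest)),
        "seed": config.seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dish_df.to_csv(out_dir / "dishes.csv", index=False)
        pooled = []
        for cond in conditions:
            t = cult.pnn_size_and_intensity(records_by_cond[cond], ctrl_records)
            t.insert(0, "condition", cond)
            pooled.append(t)
        pd.concat(pooled).to_csv(out_dir / "pnn_table.csv", index=False)
        _json_dump(report, out_dir / "comparisons.json")
        _json_dump(_run_log(config, report), out_dir / "run_log.json")
    return report
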