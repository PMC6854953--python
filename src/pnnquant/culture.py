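"""Culture-side quantification and group statistics.

Covers the dish-level readouts of the motivating experiments: PNN
density normalised to a 50 mm² reference area, per-PNN size and WFA
intensity (absolute and relative to a control group), the fraction of
parvalbumin-positive cells that carry a net, and the two-sample
comparisons (Student's t with pooled variance, or one-way ANOVA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import estimate_background
from .detection import NucleusCandidate, PNNObject
from .io import ImageStack
from .quantify import MeasurementRecord

__all__ = [
    "GroupComparisonResult",
    "DishSummary",
    "density_per_50mm2",
    "pnn_size_and_intensity",
    "pv_pnn_fraction",
    "summarize_dish",
    "compare_groups",
    "enzyme_reduction_analysis",
]

REFERENCE_AREA_MM2 = 50.0


@dataclass
class GroupComparisonResult:
    test_name: str  # "t" or "anova"
    statistic: float
    p_value: float
    group_means: tuple[float, ...]
    group_ns: tuple[int, ...]
    effect_direction: str  # "increase", "decrease" or "none"
    degenerate: bool = False  # zero pooled variance with equal means


@dataclass
class DishSummary:
    dish_id: str
    condition: str
    pnn_count: int
    imaged_area_mm2: float
    density_per_50mm2: float
    pnn_areas_um2: list[float]
    pnn_wfa_means: list[float]
    pv_count: int
    pv_with_pnn_count: int

    def __post_init__(self) -> None:
        if self.pv_with_pnn_count > self.pv_count:
            raise ValueError("pv_with_pnn_count cannot exceed pv_count")


def density_per_50mm2(pnn_count: int, imaged_area_mm2: float) -> float:
    """PNN count scaled linearly to a 50 mm² reference area."""
    if not (np.isfinite(imaged_area_mm2) and imaged_area_mm2 > 0):
        raise ValueError(f"imaged area must be positive, got {imaged_area_mm2}")
    if pnn_count < 0:
        raise ValueError("pnn_count must be >= 0")
    return pnn_count * (REFERENCE_AREA_MM2 / imaged_area_mm2)


def pnn_size_and_intensity(
    records: list[MeasurementRecord],
    control_records: list[MeasurementRecord] | None = None,
) -> pd.DataFrame:
    """Per-PNN area (µm²) and mean WFA intensity as a tidy table.

    When control records are given, ``rel_area`` / ``rel_wfa`` columns
    hold each value divided by the control-group mean, so the control
    group's relative mean is 1 by construction.
    """
    df = pd.DataFrame(
        {
            "pnn_id": [r.pnn_id for r in records],
            "image_id": [r.image_id for r in records],
            "area_um2": [r.area_um2 for r in records],
            "wfa_mean": [r.mean_intensity["wfa"] for r in records],
        }
    )
    if control_records is not None:
        area0 = float(np.mean([r.area_um2 for r in control_records]))
        wfa0 = float(np.mean([r.mean_intensity["wfa"] for r in control_records]))
        df["rel_area"] = df["area_um2"] / area0
        df["rel_wfa"] = df["wfa_mean"] / wfa0
    return df


def pv_cells(
    stack: ImageStack,
    nuclei: list[NucleusCandidate],
    k: float = 3.0,
    soma_scale: float = 2.0,
) -> list[int]:
    """Nucleus ids whose surrounding soma is parvalbumin-positive.

    A nucleus counts as PV when the mean ``pv`` intensity over a disc
    of ``soma_scale`` × its equivalent radius exceeds the image
    background by ``k`` robust SDs.
    """
    if "pv" not in stack:
        raise KeyError("stack has no 'pv' channel")
    img = stack["pv"]
    background = estimate_background(stack, [], channel="pv")
    thr = background.mean + k * background.sd
    out = []
    for nuc in nuclei:
        r = soma_scale * nuc.equivalent_radius
        r0 = max(int(np.floor(nuc.centroid[0] - r)), 0)
        r1 = min(int(np.ceil(nuc.centroid[0] + r)) + 1, img.shape[0])
        c0 = max(int(np.floor(nuc.centroid[1] - r)), 0)
        c1 = min(int(np.ceil(nuc.centroid[1] + r)) + 1, img.shape[1])
        rr = np.arange(r0, r1)[:, None] - nuc.centroid[0]
        cc = np.arange(c0, c1)[None, :] - nuc.centroid[1]
        disc = np.hypot(rr, cc) <= r
        if disc.any() and float(img[r0:r1, c0:c1][disc].mean()) > thr:
            out.append(nuc.nucleus_id)
    return out


def pv_pnn_fraction(dish: DishSummary) -> float:
    """Percentage of PV cells in the dish that carry a validated net."""
    if dish.pv_count <= 0:
        raise ValueError(f"dish {dish.dish_id}: no PV cells")
    return 100.0 * dish.pv_with_pnn_count / dish.pv_count


def summarize_dish(
    stack: ImageStack,
    objects: list[PNNObject],
    nuclei: list[NucleusCandidate],
    records: list[MeasurementRecord],
    dish_id: str,
    condition: str,
) -> DishSummary:
    """Assemble the dish-level summary from one imaged field.

    The imaged area is the full frame in mm²; PV cells come from the
    ``pv`` channel when present, and a PV cell "has a PNN" when some
    validated object links to its nucleus.
    """
    rows, cols = stack.shape
    area_mm2 = rows * cols * (stack.pixel_size * 1e-3) ** 2
    if "pv" in stack:
        pv_ids = set(pv_cells(stack, nuclei))
        linked = {obj.nucleus_id for obj in objects}
        pv_count = len(pv_ids)
        pv_with = len(pv_ids & linked)
    else:
        pv_count = pv_with = 0
    return DishSummary(
        dish_id=dish_id,
        condition=condition,
        pnn_count=len(objects),
        imaged_area_mm2=area_mm2,
        density_per_50mm2=density_per_50mm2(len(objects), area_mm2),
        pnn_areas_um2=[r.area_um2 for r in records],
        pnn_wfa_means=[r.mean_intensity["wfa"] for r in records],
        pv_count=pv_count,
        pv_with_pnn_count=pv_with,
    )


def _direction(mean_a: float, mean_b: float, p: float, alpha: float = 0.05) -> str:
    if p > alpha or mean_a == mean_b:
        return "none"
    return "increase" if mean_b > mean_a else "decrease"


def compare_groups(
    values_a,
    values_b,
    test: str = "t",
    extra_groups: list | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> GroupComparisonResult:
    """Two-sample Student's t (pooled variance; ``equal_var=False``
    switches to Welch) or one-way ANOVA.

    Direction is reported for the second group relative to the first
    and only when the test is significant at ``alpha``.  Identical
    constant groups (zero pooled variance, equal means) return the
    p = 1 convention with the ``degenerate`` flag set.
    """
    groups = [np.asarray(values_a, float), np.asarray(values_b, float)]
    if extra_groups:
        groups += [np.asarray(g, float) for g in extra_groups]
    if test == "anova" and len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    means = tuple(float(g.mean()) for g in groups)
    ns = tuple(int(len(g)) for g in groups)

    pooled_var = float(np.concatenate([g - g.mean() for g in groups]).var())
    if pooled_var == 0.0 and len(set(means)) == 1:
        return GroupComparisonResult(
            test_name=test, statistic=0.0, p_value=1.0,
            group_means=means, group_ns=ns, effect_direction="none", degenerate=True,
        )

    if test == "t":
        if len(groups) != 2:
            raise ValueError("the t-test takes exactly two groups")
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
    elif test == "anova":
        stat, p = stats.f_oneway(*groups)
    else:
        raise ValueError(f"unknown test {test!r} (expected 't' or 'anova')")
    direction = _direction(means[0], means[1], float(p), alpha)
    return GroupComparisonResult(
        test_name=test, statistic=float(stat), p_value=float(p),
        group_means=means, group_ns=ns, effect_direction=direction,
    )


def enzyme_reduction_analysis(
    control_records: list[MeasurementRecord],
    treated_records: list[MeasurementRecord],
    channels: tuple[str, ...] = ("wfa", "comparison"),
    test: str = "t",
) -> dict[str, GroupComparisonResult]:
    """Per-channel comparison of ring intensities after an
    enzyme-style treatment.

    Intensities are expressed relative to the control-group mean of the
    same channel (so control averages 1) and compared across conditions;
    the result reports direction and significance per channel.
    """
    out: dict[str, GroupComparisonResult] = {}
    for ch in channels:
        ctrl = np.array([r.mean_intensity[ch] for r in control_records])
        trt = np.array([r.mean_intensity[ch] for r in treated_records])
        ref = ctrl.mean()
        if ref <= 0:
            raise ValueError(f"control mean of channel {ch!r} is not positive")
        out[ch] = compare_groups(ctrl / ref, trt / ref, test=test)
    return out
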