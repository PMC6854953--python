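"""Culture quantification: density scaling, group tests vs closed
forms, PV-gated fractions, enzyme-effect simulations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnnquant.culture import (
    DishSummary,
    compare_groups,
    density_per_50mm2,
    enzyme_reduction_analysis,
    pnn_size_and_intensity,
    pv_pnn_fraction,
    summarize_dish,
)
from pnnquant.detection import detect_and_segment
from pnnquant.experiments import enzyme_direction
from pnnquant.quantify import MeasurementRecord, measure_all
from pnnquant.synthetic import GeneratorConfig, culture_config, generate_scene


# --- density ---------------------------------------------------------------


def test_density_reference_area():
    assert density_per_50mm2(10, 50.0) == pytest.approx(10.0)
    assert density_per_50mm2(5, 25.0) == pytest.approx(10.0)
    assert density_per_50mm2(0, 3.0) == 0.0


@settings(max_examples=50, deadline=None)
@given(
    count=st.integers(0, 1000),
    area=st.floats(0.01, 500, allow_nan=False),
    k=st.integers(1, 5),
)
def test_density_linearity(count, area, k):
    d = density_per_50mm2(count, area)
    assert density_per_50mm2(k * count, area) == pytest.approx(k * d, rel=1e-12)
    assert density_per_50mm2(count, k * area) == pytest.approx(d / k, rel=1e-12)


def test_density_invalid_area():
    with pytest.raises(ValueError):
        density_per_50mm2(3, 0.0)


# --- group comparisons -----------------------------------------------------


def test_t_statistic_matches_closed_form():
    """{1,2,3} vs {4,5,6}: pooled s² = 1, t = -3·sqrt(3/2)."""
    res = compare_groups([1, 2, 3], [4, 5, 6], test="t")
    expected_t = -3.0 * np.sqrt(1.5)
    assert abs(res.statistic - expected_t) < 1e-10
    # textbook p from the t CDF with 4 df, evaluated independently
    from scipy.special import betainc

    df = 4
    x = df / (df + expected_t**2)
    p = betainc(df / 2, 0.5, x)
    assert abs(res.p_value - p) < 1e-10
    assert res.effect_direction == "increase"


def test_anova_matches_hand_computation():
    groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [6.0, 7.0, 8.0]]
    res = compare_groups(groups[0], groups[1], test="anova", extra_groups=[groups[2]])
    # brute-force decomposition of sums of squares
    grand = np.mean([v for g in groups for v in g])
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - np.mean(g)) ** 2 for g in groups for v in g)
    f = (ss_between / 2) / (ss_within / 6)
    assert abs(res.statistic - f) < 1e-10


def test_identical_groups_degenerate():
    res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert res.effect_direction == "none"
    assert res.degenerate


def test_insufficient_n():
    with pytest.raises(ValueError, match="at least 2"):
        compare_groups([1.0], [2.0, 3.0])


# --- per-PNN size / intensity ----------------------------------------------


def _record(area_um2, wfa):
    return MeasurementRecord(
        pnn_id=0, area_px=area_um2 * 4, area_um2=area_um2,
        mean_intensity={"wfa": wfa},
    )


def test_area_arithmetic():
    # 200 mask pixels at pixel_size 0.5 um -> 50 um^2
    assert 200 * 0.5**2 == pytest.approx(50.0)
    tbl = pnn_size_and_intensity([_record(50.0, 0.5)])
    assert tbl["area_um2"].iloc[0] == pytest.approx(50.0)


def test_control_relative_mean_is_one():
    ctrl = [_record(40.0, 0.4), _record(60.0, 0.6)]
    tbl = pnn_size_and_intensity(ctrl, control_records=ctrl)
    assert tbl["rel_area"].mean() == pytest.approx(1.0)
    assert tbl["rel_wfa"].mean() == pytest.approx(1.0)


def test_radius_scaled_scenes_recover_area_ratio():
    """Rings rendered 1.3x larger should measure ~1.3x the area."""
    ratios = []
    for seed in (81, 82):
        ctrl_cfg = culture_config(n_cells=12, seed=seed, image_shape=(768, 768))
        trt_cfg = culture_config(
            treated=True, radius_scale=1.3, intensity_scale=1.0,
            n_cells=12, seed=seed + 10, image_shape=(768, 768),
        )
        trt_cfg.frac_pnn = ctrl_cfg.frac_pnn = 1.0
        areas = {}
        for name, cfg in (("ctrl", ctrl_cfg), ("trt", trt_cfg)):
            stack, _ = generate_scene(cfg)
            objects, _, _ = detect_and_segment(stack)
            recs = measure_all(stack, objects, channels=("wfa",))
            areas[name] = np.mean([r.area_um2 for r in recs])
        ratios.append(areas["trt"] / areas["ctrl"])
    assert np.mean(ratios) == pytest.approx(1.3, rel=0.10)


# --- PV fraction -----------------------------------------------------------


def test_pv_fraction_arithmetic():
    dish = DishSummary(
        dish_id="d", condition="ctrl", pnn_count=3, imaged_area_mm2=1.0,
        density_per_50mm2=150.0, pnn_areas_um2=[], pnn_wfa_means=[],
        pv_count=10, pv_with_pnn_count=3,
    )
    assert pv_pnn_fraction(dish) == pytest.approx(30.0)


def test_pv_fraction_zero_pv_errors():
    dish = DishSummary(
        dish_id="d", condition="c", pnn_count=0, imaged_area_mm2=1.0,
        density_per_50mm2=0.0, pnn_areas_um2=[], pnn_wfa_means=[],
        pv_count=0, pv_with_pnn_count=0,
    )
    with pytest.raises(ValueError, match="no PV cells"):
        pv_pnn_fraction(dish)


def test_pv_fraction_recovered_from_scenes():
    """All-PV scenes with exactly 40% of cells ring-bearing recover a
    40% PV-PNN fraction within 3 points."""
    fracs = []
    for seed in (91, 92):
        cfg = GeneratorConfig(
            image_shape=(1024, 1024), n_cells=50, frac_pnn=0.4,
            frac_pv=1.0, exact_count=True, seed=seed,
        )
        stack, gt = generate_scene(cfg)
        from pnnquant.detection import detect_nuclei

        objects, nuclei, _ = detect_and_segment(stack)
        recs = measure_all(stack, objects, channels=("wfa",))
        dish = summarize_dish(stack, objects, nuclei, recs, "d", "ctrl")
        fracs.append(pv_pnn_fraction(dish))
    assert np.mean(fracs) == pytest.approx(40.0, abs=3.0)


def test_missing_pv_channel_errors(processed_scene):
    from pnnquant.culture import pv_cells
    from pnnquant.io import ImageStack

    stack = processed_scene["stack"]
    partial = ImageStack(
        channels={k: v for k, v in stack.channels.items() if k != "pv"},
        pixel_size=stack.pixel_size,
    )
    with pytest.raises(KeyError, match="pv"):
        pv_cells(partial, processed_scene["nuclei"])


# --- enzyme reduction ------------------------------------------------------


def test_enzyme_identical_conditions_nonsignificant():
    recs = [_record(50.0, v) for v in (0.4, 0.5, 0.6, 0.7)]
    out = enzyme_reduction_analysis(recs, recs, channels=("wfa",))
    assert out["wfa"].effect_direction == "none"
    assert out["wfa"].p_value == 1.0


def test_enzyme_both_channels_reduced():
    out = enzyme_direction(seed=7)
    for ch in ("wfa", "comparison"):
        assert out[ch]["p_value"] < 0.05
        assert out[ch]["direction"] == "decrease"


def test_enzyme_targeted_channel_only():
    out = enzyme_direction(seed=11, scale_channels=("comparison",))
    assert out["comparison"]["p_value"] < 0.05
    assert out["comparison"]["direction"] == "decrease"
    assert out["wfa"]["direction"] == "none"
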