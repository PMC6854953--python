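"""Mean-intensity and Spearman operations vs independent oracles."""

import numpy as np
import pytest
from scipy import stats

from pnnquant.detection import PNNObject
from pnnquant.io import ImageStack
from pnnquant.quantify import (
    DegenerateInputError,
    MeasurementRecord,
    colocalize,
    measure_all,
    measure_intensity,
    spearman,
)


def _object_from_mask(mask):
    rows, cols = np.nonzero(mask)
    return PNNObject(
        pnn_id=0, center=(float(rows.mean()), float(cols.mean())),
        radius=5.0, detection_score=1.0, nucleus_id=0,
        ring_rows=rows, ring_cols=cols,
    )


def test_mean_over_constant_region():
    img = np.full((20, 20), 0.4)
    mask = np.zeros((20, 20), bool)
    mask[5:10, 5:10] = True
    stack = ImageStack(channels={"wfa": img}, pixel_size=1.0)
    assert measure_intensity(stack, _object_from_mask(mask), "wfa") == pytest.approx(0.4)
    # optional per-image background subtraction
    assert measure_intensity(stack, _object_from_mask(mask), "wfa", background=0.1) == pytest.approx(0.3)


def test_mean_of_two_pixels():
    img = np.zeros((4, 4))
    img[1, 1] = 1.0
    mask = np.zeros((4, 4), bool)
    mask[1, 1] = mask[2, 2] = True
    stack = ImageStack(channels={"wfa": img}, pixel_size=1.0)
    assert measure_intensity(stack, _object_from_mask(mask), "wfa") == pytest.approx(0.5)


def test_mean_matches_pixel_loop_oracle(rng):
    """Brute-force pixel iteration agrees to 1e-12 on random pairs."""
    stack_shape = (40, 40)
    for _ in range(100):
        img = rng.random(stack_shape)
        mask = rng.random(stack_shape) < 0.2
        if not mask.any():
            mask[0, 0] = True
        total, count = 0.0, 0
        for i in range(stack_shape[0]):
            for j in range(stack_shape[1]):
                if mask[i, j]:
                    total += img[i, j]
                    count += 1
        oracle = total / count
        stack = ImageStack(channels={"wfa": img}, pixel_size=1.0)
        assert abs(measure_intensity(stack, _object_from_mask(mask), "wfa") - oracle) < 1e-12


def test_empty_mask_and_unknown_channel_error():
    stack = ImageStack(channels={"wfa": np.ones((4, 4))}, pixel_size=1.0)
    obj = PNNObject(pnn_id=0, center=(1, 1), radius=1, detection_score=1, nucleus_id=0)
    with pytest.raises(ValueError, match="empty"):
        measure_intensity(stack, obj, "wfa")
    mask = np.ones((4, 4), bool)
    with pytest.raises(KeyError):
        measure_intensity(stack, _object_from_mask(mask), "myc")


def test_measure_all_consistent_with_direct_calls(processed_scene):
    stack = processed_scene["stack"]
    for obj, rec in zip(processed_scene["objects"], processed_scene["records"]):
        assert rec.mean_intensity["wfa"] == measure_intensity(stack, obj, "wfa")
        assert rec.area_px == obj.ring_area_px
        assert rec.area_um2 == pytest.approx(obj.ring_area_px * 0.25)


def test_measure_all_empty():
    stack = ImageStack(channels={"wfa": np.ones((4, 4))}, pixel_size=1.0)
    assert measure_all(stack, [], channels=("wfa",)) == []


# --- spearman --------------------------------------------------------------


def test_monotone_curves_give_plus_minus_one(rng):
    x = np.sort(rng.random(15))
    up = np.column_stack([x, np.exp(x)])
    down = np.column_stack([x, -(x**3)])
    assert spearman(up).rho == pytest.approx(1.0)
    assert spearman(down).rho == pytest.approx(-1.0)


def test_spearman_matches_scipy_with_ties(rng):
    """Rank-then-Pearson equals the library implementation, ties included."""
    for _ in range(20):
        x = rng.integers(0, 5, size=10).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=10).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        ours = spearman(np.column_stack([x, y])).rho
        ref = stats.spearmanr(x, y).statistic
        assert abs(ours - ref) < 1e-12


@pytest.mark.parametrize("transform", [np.exp, lambda v: v**3])
def test_spearman_invariant_under_monotone_transform(rng, transform):
    x = rng.random(30)
    y = rng.random(30)
    base = spearman(np.column_stack([x, y])).rho
    assert spearman(np.column_stack([transform(x), y])).rho == pytest.approx(base, abs=1e-12)
    assert spearman(np.column_stack([x, transform(y)])).rho == pytest.approx(base, abs=1e-12)


def test_spearman_input_errors():
    with pytest.raises(ValueError, match="at least 3"):
        spearman([(1, 2), (3, 4)])
    with pytest.raises(DegenerateInputError):
        spearman([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])


def test_permutation_p_small_for_strong_association(rng):
    x = np.arange(20.0)
    y = x + rng.normal(0, 0.1, 20)
    res = spearman(np.column_stack([x, y]), permutation_p=True, n_permutations=999, seed=0)
    assert res.p_value < 0.01


# --- colocalize ------------------------------------------------------------


def _records_from_pairs(pairs):
    return [
        MeasurementRecord(
            pnn_id=i, area_px=10, area_um2=2.5,
            mean_intensity={"wfa": float(a), "comparison": float(b)},
        )
        for i, (a, b) in enumerate(pairs)
    ]


def test_identity_channel_gives_rho_one(rng):
    vals = rng.random(10)
    recs = _records_from_pairs(np.column_stack([vals, vals]))
    assert colocalize(recs).rho == pytest.approx(1.0)


def test_independent_channel_gives_near_zero_rho():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        recs = _records_from_pairs(np.column_stack([rng.random(1000), rng.random(1000)]))
        assert abs(colocalize(recs).rho) < 0.1
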