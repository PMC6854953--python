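"""Ring and nucleus detection against constructions and ground truth."""

import numpy as np
import pytest

from conftest import match_truth
from pnnquant.detection import (
    DetectionParams,
    GateParams,
    NucleusCandidate,
    PNNObject,
    RingCandidate,
    RingParams,
    detect_and_segment,
    detect_nuclei,
    detect_rings,
    segment_ring_area,
    validate_with_nuclei,
)
from pnnquant.io import ImageStack
from pnnquant.synthetic import (
    GeneratorConfig,
    NoiseModel,
    add_nucleus,
    add_ring_texture,
    generate_scene,
    true_ring_mask,
)


def _noise_stack(shape=(256, 256), seed=0, channels=("nuclear", "wfa")):
    rng = np.random.default_rng(seed)
    return ImageStack(
        channels={
            n: np.clip(0.05 + 0.01 * rng.standard_normal(shape), 0, 1)
            for n in channels
        },
        pixel_size=0.5,
    )


# --- nuclei ----------------------------------------------------------------


def test_blank_nuclear_channel_gives_no_nuclei():
    assert detect_nuclei(_noise_stack()) == []


def test_single_nucleus_centroid():
    stack = _noise_stack(shape=(128, 128), seed=3)
    add_nucleus(stack.channels["nuclear"], (64.0, 64.0), 4.0, 0.6)
    nuclei = detect_nuclei(stack)
    assert len(nuclei) == 1
    assert np.hypot(nuclei[0].centroid[0] - 64, nuclei[0].centroid[1] - 64) < 2.0


def test_fifty_nuclei_matched_one_to_one():
    cfg = GeneratorConfig(image_shape=(1024, 1024), n_cells=50, frac_pnn=0.0, seed=8)
    stack, gt = generate_scene(cfg)
    nuclei = detect_nuclei(stack)
    assert len(nuclei) == 50
    remaining = list(gt.cells)
    for nuc in nuclei:
        best = min(
            remaining,
            key=lambda c: np.hypot(nuc.centroid[0] - c.center[0], nuc.centroid[1] - c.center[1]),
        )
        d = np.hypot(nuc.centroid[0] - best.center[0], nuc.centroid[1] - best.center[1])
        assert d < 3.0
        remaining.remove(best)
    assert remaining == []


def test_missing_nuclear_channel():
    stack = _noise_stack(channels=("wfa",))
    with pytest.raises(KeyError, match="nuclear"):
        detect_nuclei(stack)


# --- rings -----------------------------------------------------------------


def test_noise_only_wfa_gives_no_rings():
    assert detect_rings(_noise_stack(seed=5)) == []


def test_single_planted_annulus():
    stack = _noise_stack(shape=(256, 256), seed=7)
    rng = np.random.default_rng(0)
    add_ring_texture(stack.channels["wfa"], (100.0, 100.0), 12.0, 2.5, 0.6, rng)
    cands = detect_rings(stack)
    assert len(cands) == 1
    c = cands[0]
    assert np.hypot(c.center[0] - 100, c.center[1] - 100) < 2.0
    assert abs(c.radius - 12.0) < 2.0


def test_twenty_planted_annuli_matched():
    cfg = GeneratorConfig(
        image_shape=(768, 768), n_cells=20, frac_pnn=1.0, exact_count=True, seed=13
    )
    stack, gt = generate_scene(cfg)
    cands = detect_rings(stack)
    assert len(cands) == 20
    remaining = list(gt.pnn_cells)
    for c in cands:
        best = min(
            remaining,
            key=lambda t: np.hypot(c.center[0] - t.center[0], c.center[1] - t.center[1]),
        )
        assert np.hypot(c.center[0] - best.center[0], c.center[1] - best.center[1]) < 3.0
        remaining.remove(best)


def test_bad_radius_range():
    with pytest.raises(ValueError, match="radius range"):
        detect_rings(_noise_stack(), RingParams(r_min=20, r_max=20))


# --- gating ----------------------------------------------------------------


def _nucleus(nid, r, c):
    return NucleusCandidate(
        nucleus_id=nid, centroid=(r, c), equivalent_radius=4.0,
        coords=np.array([[int(r), int(c)]]),
    )


def test_gate_keeps_candidate_with_inner_nucleus():
    cand = RingCandidate(center=(50.0, 50.0), radius=15.0, detection_score=1.0)
    objs = validate_with_nuclei([cand], [_nucleus(0, 52.0, 49.0)])
    assert len(objs) == 1 and objs[0].nucleus_id == 0


def test_gate_rejects_candidate_without_nucleus():
    cand = RingCandidate(center=(50.0, 50.0), radius=15.0, detection_score=1.0)
    assert validate_with_nuclei([cand], [_nucleus(0, 90.0, 90.0)]) == []


def test_gate_never_increases_count_and_is_literal(processed_scene):
    objs = processed_scene["objects"]
    nuclei = {n.nucleus_id: n for n in processed_scene["nuclei"]}
    log = processed_scene["log"]
    assert log["validated"] <= log["ring_candidates"]
    for obj in objs:
        nuc = nuclei[obj.nucleus_id]
        d = np.hypot(obj.center[0] - nuc.centroid[0], obj.center[1] - nuc.centroid[1])
        assert d < obj.radius  # gate predicate, gate_factor 1


def test_nucleus_assigned_to_best_candidate_only():
    nucleus = _nucleus(0, 50.0, 50.0)
    good = RingCandidate(center=(50.0, 50.0), radius=15.0, detection_score=2.0)
    worse = RingCandidate(center=(52.0, 50.0), radius=15.0, detection_score=1.0)
    objs = validate_with_nuclei([worse, good], [nucleus])
    assert len(objs) == 1
    assert objs[0].detection_score == 2.0


def test_pnn_free_cells_and_ringless_artefacts_are_excluded():
    """20 ring-bearing cells + 10 ring-free cells + 3 nucleus-free ring
    artefacts must yield exactly the 20 real nets."""
    cfg = GeneratorConfig(
        image_shape=(1024, 1024), n_cells=30, frac_pnn=20 / 30,
        exact_count=True, seed=23,
    )
    stack, gt = generate_scene(cfg)
    assert len(gt.pnn_cells) == 20
    rng = np.random.default_rng(99)
    centers = np.array([c.center for c in gt.cells])
    planted = 0
    while planted < 3:
        p = rng.uniform(60, 960, size=2)
        if np.min(np.hypot(*(centers - p).T)) > 60:
            add_ring_texture(stack.channels["wfa"], tuple(p), 18.0, 2.5, 0.6, rng)
            planted += 1
    objects, _, log = detect_and_segment(stack)
    assert log["ring_candidates"] == 23
    assert len(objects) == 20


# --- segmentation ----------------------------------------------------------


def test_uniform_annulus_segments_exactly():
    shape = (128, 128)
    wfa = np.zeros(shape)
    geo = true_ring_mask(shape, (60.0, 60.0), 14.0, 2.5)
    wfa[geo] = 0.5
    stack = ImageStack(channels={"wfa": wfa}, pixel_size=0.5)
    obj = PNNObject(pnn_id=0, center=(60.0, 60.0), radius=14.0, detection_score=1.0, nucleus_id=0)
    seg = segment_ring_area(stack, obj)
    assert np.array_equal(seg.ring_mask(shape), geo)


def test_zero_signal_annulus_is_dropped():
    stack = ImageStack(channels={"wfa": np.zeros((64, 64))}, pixel_size=0.5)
    obj = PNNObject(pnn_id=0, center=(32.0, 32.0), radius=10.0, detection_score=1.0, nucleus_id=0)
    assert segment_ring_area(stack, obj) is None


def test_annulus_outside_image_errors():
    stack = ImageStack(channels={"wfa": np.zeros((64, 64))}, pixel_size=0.5)
    obj = PNNObject(pnn_id=0, center=(500.0, 500.0), radius=10.0, detection_score=1.0, nucleus_id=0)
    with pytest.raises(ValueError, match="outside"):
        segment_ring_area(stack, obj)


def test_segmented_area_close_to_true_ring_area(processed_scene):
    stack = processed_scene["stack"]
    for obj in processed_scene["objects"]:
        cell = match_truth(obj, processed_scene["truth"].pnn_cells)
        true_area = true_ring_mask(stack.shape, cell.center, cell.pnn_radius, cell.pnn_thickness).sum()
        assert obj.ring_area_px == pytest.approx(true_area, rel=0.15)


def test_detection_is_deterministic(small_scene):
    stack, _ = small_scene
    o1, n1, l1 = detect_and_segment(stack)
    o2, n2, l2 = detect_and_segment(stack)
    assert l1 == l2
    for a, b in zip(o1, o2):
        assert a.center == b.center and a.radius == b.radius
        assert np.array_equal(a.ring_rows, b.ring_rows)
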