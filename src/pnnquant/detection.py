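"""PNN detection: ring finding in the WFA channel, nucleus gating, and
WFA-positive ring-area segmentation.

The procedure mirrors the published workflow: circular shapes are
identified in the WFA channel, each candidate circle is then checked
against the nuclear channel to confirm it surrounds a cell, and for
every validated net the WFA-positive pixels of the annulus are selected
as the measurement region.

Ring finding uses edge extraction (Canny) followed by a circular Hough
accumulator over a configurable radius range, with deterministic
non-maximum suppression; tie-breaking is everywhere by
(score desc, row asc, col asc) so identical inputs give identical
object lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import feature, measure, transform

from .io import ImageStack

__all__ = [
    "NucleusParams",
    "RingParams",
    "GateParams",
    "SegmentParams",
    "DetectionParams",
    "NucleusCandidate",
    "RingCandidate",
    "PNNObject",
    "detect_nuclei",
    "detect_rings",
    "validate_with_nuclei",
    "segment_ring_area",
    "detect_and_segment",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass
class NucleusParams:
    """Nucleus detection: Gaussian smoothing, robust thresholding
    (median + k·MAD of the smoothed channel), connected components,
    area gate in pixels."""

    smooth_sigma: float = 2.0
    k_mad: float = 6.0
    area_min: float = 15.0
    area_max: float = 400.0


@dataclass
class RingParams:
    """Ring finding: Canny edges then a circular Hough accumulator over
    radii [r_min, r_max]; peaks below ``accum_threshold`` (normalised
    votes) are discarded and survivors are non-max suppressed at
    ``min_spacing`` pixels between centres."""

    r_min: int = 8
    r_max: int = 30
    accum_threshold: float = 0.35
    min_spacing: float = 16.0
    canny_sigma: float = 2.0
    refine_halfwidth: float = 7.0  # px band for radial-centroid refinement

    def radii(self) -> np.ndarray:
        if self.r_min >= self.r_max:
            raise ValueError(f"empty radius range [{self.r_min}, {self.r_max}]")
        return np.arange(self.r_min, self.r_max + 1)


@dataclass
class GateParams:
    """A candidate survives iff some nucleus centroid lies within its
    circle scaled by gate_factor; nearest such nucleus is assigned,
    each nucleus to at most one candidate (best score wins)."""

    gate_factor: float = 1.0


@dataclass
class SegmentParams:
    """WFA-positive selection inside the annulus radius ± thickness;
    the local background threshold is median + k_bg·MAD of an annular
    shell outside the ring."""

    thickness: float = 2.5
    k_bg: float = 2.0
    shell_gap: float = 2.0
    shell_width: float = 5.0


@dataclass
class DetectionParams:
    nucleus: NucleusParams = field(default_factory=NucleusParams)
    ring: RingParams = field(default_factory=RingParams)
    gate: GateParams = field(default_factory=GateParams)
    segment: SegmentParams = field(default_factory=SegmentParams)


# ---------------------------------------------------------------------------
# results


@dataclass
class NucleusCandidate:
    nucleus_id: int
    centroid: tuple[float, float]
    equivalent_radius: float
    coords: np.ndarray  # (k, 2) pixel coordinates of the region


@dataclass
class RingCandidate:
    center: tuple[float, float]
    radius: float
    detection_score: float


@dataclass
class PNNObject:
    """A validated perineuronal net: circle, linked nucleus, and (after
    segmentation) the WFA-positive annular mask as pixel coordinates."""

    pnn_id: int
    center: tuple[float, float]
    radius: float
    detection_score: float
    nucleus_id: int
    ring_rows: np.ndarray | None = None
    ring_cols: np.ndarray | None = None

    @property
    def ring_area_px(self) -> int:
        return 0 if self.ring_rows is None else int(len(self.ring_rows))

    def ring_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        if self.ring_rows is not None:
            mask[self.ring_rows, self.ring_cols] = True
        return mask


# ---------------------------------------------------------------------------
# operations


def detect_nuclei(stack: ImageStack, params: NucleusParams | None = None) -> list[NucleusCandidate]:
    """Find nucleus candidates in the ``nuclear`` channel.

    Smoothed robust thresholding + connected components, area-filtered,
    sorted by centroid (row, then col).
    """
    params = params or NucleusParams()
    if "nuclear" not in stack:
        raise KeyError("stack has no 'nuclear' channel")
    img = ndimage.gaussian_filter(stack["nuclear"], params.smooth_sigma)
    med = np.median(img)
    mad = np.median(np.abs(img - med))
    thr = med + params.k_mad * max(mad, 1e-6)
    labels = measure.label(img > thr, connectivity=2)
    out: list[NucleusCandidate] = []
    for region in measure.regionprops(labels, intensity_image=img):
        # the robust threshold catches the smoothed skirt of the blob;
        # re-threshold each region at half its peak above background so
        # the mask tracks the nucleus itself
        half = med + 0.5 * (float(region.intensity_max) - med)
        keep = img[region.coords[:, 0], region.coords[:, 1]] > half
        coords = region.coords[keep]
        area = len(coords)
        if not (params.area_min <= area <= params.area_max):
            continue
        centroid = coords.mean(axis=0)
        out.append(
            NucleusCandidate(
                nucleus_id=-1,
                centroid=(float(centroid[0]), float(centroid[1])),
                equivalent_radius=float(np.sqrt(area / np.pi)),
                coords=coords.copy(),
            )
        )
    out.sort(key=lambda n: n.centroid)
    for i, n in enumerate(out):
        n.nucleus_id = i
    return out


def detect_rings(stack: ImageStack, params: RingParams | None = None) -> list[RingCandidate]:
    """Find circular PNN candidates in the ``wfa`` channel.

    Canny edges feed a circular Hough accumulator over the configured
    radius range; normalised peak votes below ``accum_threshold`` are
    discarded and overlapping candidates are suppressed keeping the
    higher score.  Output order is (score desc, row asc, col asc).
    """
    params = params or RingParams()
    if "wfa" not in stack:
        raise KeyError("stack has no 'wfa' channel")
    radii = params.radii()
    edges = feature.canny(stack["wfa"], sigma=params.canny_sigma)
    if not edges.any():
        return []
    hspaces = transform.hough_circle(edges, radii, normalize=True)
    accums, cx, cy, rads = transform.hough_circle_peaks(
        hspaces,
        radii,
        min_xdistance=int(params.min_spacing),
        min_ydistance=int(params.min_spacing),
        threshold=params.accum_threshold,
        num_peaks=np.inf,
        total_num_peaks=np.inf,
    )
    cands = [
        RingCandidate(center=(float(y), float(x)), radius=float(r), detection_score=float(a))
        for a, x, y, r in zip(accums, cx, cy, rads)
    ]
    cands.sort(key=lambda c: (-c.detection_score, c.center[0], c.center[1]))
    # greedy NMS: keep best-scoring candidate, drop others with a nearby centre
    kept: list[RingCandidate] = []
    sp2 = params.min_spacing**2
    for c in cands:
        if all(
            (c.center[0] - k.center[0]) ** 2 + (c.center[1] - k.center[1]) ** 2 >= sp2
            for k in kept
        ):
            kept.append(c)
    # the accumulator peak often sits on the inner or outer edge of the
    # annulus; pull the radius back to the ring's radial intensity centroid
    for c in kept:
        c.radius = _refine_radius(stack["wfa"], c.center, c.radius, params.refine_halfwidth)
    return kept


def _refine_radius(wfa: np.ndarray, center: tuple[float, float], r0: float, halfwidth: float) -> float:
    """Radius re-estimate: intensity-weighted mean distance from the
    centre within a band around the Hough radius, iterated once."""
    rows, cols = wfa.shape
    r = r0
    for _ in range(2):
        band_out = r + halfwidth
        rs = max(int(np.floor(center[0] - band_out)), 0)
        re = min(int(np.ceil(center[0] + band_out)) + 1, rows)
        cs = max(int(np.floor(center[1] - band_out)), 0)
        ce = min(int(np.ceil(center[1] + band_out)) + 1, cols)
        rr = np.arange(rs, re)[:, None] - center[0]
        cc = np.arange(cs, ce)[None, :] - center[1]
        dist = np.hypot(rr, cc)
        band = (dist >= max(r - halfwidth, 1.0)) & (dist <= band_out)
        if not band.any():
            return r
        patch = wfa[rs:re, cs:ce]
        w = patch[band] - np.median(patch[band])
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            return r
        r = float((w * dist[band]).sum() / w.sum())
    return r


def validate_with_nuclei(
    candidates: list[RingCandidate],
    nuclei: list[NucleusCandidate],
    params: GateParams | None = None,
) -> list[PNNObject]:
    """Keep candidates whose circle contains a nucleus centroid.

    The nearest in-circle nucleus is linked; each nucleus backs at most
    one candidate, with the better detection score winning (candidates
    are processed in score order).
    """
    params = params or GateParams()
    taken: set[int] = set()
    objects: list[PNNObject] = []
    ordered = sorted(candidates, key=lambda c: (-c.detection_score, c.center[0], c.center[1]))
    for cand in ordered:
        best_id, best_d = None, np.inf
        for nuc in nuclei:
            if nuc.nucleus_id in taken:
                continue
            d = np.hypot(
                cand.center[0] - nuc.centroid[0], cand.center[1] - nuc.centroid[1]
            )
            if d < cand.radius * params.gate_factor and d < best_d:
                best_id, best_d = nuc.nucleus_id, d
        if best_id is not None:
            taken.add(best_id)
            objects.append(
                PNNObject(
                    pnn_id=len(objects),
                    center=cand.center,
                    radius=cand.radius,
                    detection_score=cand.detection_score,
                    nucleus_id=best_id,
                )
            )
    return objects


def segment_ring_area(
    stack: ImageStack, obj: PNNObject, params: SegmentParams | None = None
) -> PNNObject | None:
    """Select the WFA-positive pixels of the annulus radius ± thickness.

    The local background threshold is median + k_bg·MAD of an annular
    shell just outside the ring.  Returns a new object with the mask
    coordinates populated, or None when the mask comes out empty (the
    caller logs the drop).
    """
    params = params or SegmentParams()
    wfa = stack["wfa"]
    rows, cols = wfa.shape
    r_out = obj.radius + params.thickness
    shell_out = r_out + params.shell_gap + params.shell_width
    r0, r1 = obj.center[0] - shell_out, obj.center[0] + shell_out
    c0, c1 = obj.center[1] - shell_out, obj.center[1] + shell_out
    if r1 < 0 or c1 < 0 or r0 >= rows or c0 >= cols:
        raise ValueError(f"annulus of object {obj.pnn_id} lies outside the image")
    rs, re = max(int(np.floor(r0)), 0), min(int(np.ceil(r1)) + 1, rows)
    cs, ce = max(int(np.floor(c0)), 0), min(int(np.ceil(c1)) + 1, cols)
    rr = np.arange(rs, re)[:, None] - obj.center[0]
    cc = np.arange(cs, ce)[None, :] - obj.center[1]
    dist = np.hypot(rr, cc)
    annulus = np.abs(dist - obj.radius) <= params.thickness
    shell = (dist >= r_out + params.shell_gap) & (dist <= shell_out)
    patch = wfa[rs:re, cs:ce]
    if shell.any():
        bg = patch[shell]
        med = np.median(bg)
        mad = np.median(np.abs(bg - med))
        thr = med + params.k_bg * max(mad, 1e-6)
    else:
        thr = 0.0
    sel = annulus & (patch > thr)
    if not sel.any():
        return None
    pr, pc = np.nonzero(sel)
    return replace(obj, ring_rows=pr + rs, ring_cols=pc + cs)


def detect_and_segment(
    stack: ImageStack, params: DetectionParams | None = None
) -> tuple[list[PNNObject], list[NucleusCandidate], dict[str, int]]:
    """Full detection pass: nuclei, rings, gating, segmentation.

    Returns the segmented objects (re-numbered 0..n-1), the nucleus
    list, and a per-stage count log including how many objects were
    dropped for an empty ring mask.
    """
    params = params or DetectionParams()
    nuclei = detect_nuclei(stack, params.nucleus)
    rings = detect_rings(stack, params.ring)
    validated = validate_with_nuclei(rings, nuclei, params.gate)
    segmented: list[PNNObject] = []
    dropped = 0
    for obj in validated:
        seg = segment_ring_area(stack, obj, params.segment)
        if seg is None:
            dropped += 1  # empty ring mask
            continue
        seg.pnn_id = len(segmented)
        segmented.append(seg)
    log = {
        "nuclei": len(nuclei),
        "ring_candidates": len(rings),
        "validated": len(validated),
        "segmented": len(segmented),
        "dropped_empty_mask": dropped,
    }
    return segmented, nuclei, log
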