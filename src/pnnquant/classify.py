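"""Comparison-channel phenotype calls and the population census.

Each validated net is scored for two independent phenotypes of the
tagged protein:

* **surface-positive** — signal on the net itself: the ring-mask mean
  in the comparison channel sits ``k_surface`` background SDs above the
  image background;
* **intracellular-punctate** — vesicle-like dots in the soma: at least
  ``m`` local maxima in the comparison channel inside the soma zone
  (ring interior minus nucleus), each ``k_puncta`` SDs above
  background.

A cell may be both, either, or neither.  The census reports the
percentage of detected PNN-positive cells carrying each phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .detection import NucleusCandidate, PNNObject
from .io import ImageStack
from .quantify import MeasurementRecord

__all__ = [
    "ClassifyParams",
    "BackgroundStats",
    "CellPhenotype",
    "PopulationFractions",
    "estimate_background",
    "classify_surface",
    "detect_puncta",
    "classify_all",
    "census",
]


@dataclass
class ClassifyParams:
    k_surface: float = 3.0  # z-score threshold for the surface call
    k_puncta: float = 3.0  # z-score threshold for one punctum
    min_puncta: int = 3  # puncta needed for a positive intracellular call
    puncta_min_spacing: int = 3  # px between accepted local maxima
    soma_margin: float = 7.0  # px kept clear of the ring's inner edge
    smooth_sigma: float = 1.0  # px, pre-smoothing for maxima detection


@dataclass
class BackgroundStats:
    """Robust background of one channel: median and 1.4826·MAD of the
    pixels away from all detected objects."""

    mean: float
    sd: float


@dataclass
class CellPhenotype:
    pnn_id: int
    surface_positive: bool
    intracellular_punctate: bool
    surface_score: float
    puncta_count: int


@dataclass
class PopulationFractions:
    n_pnn_cells: int
    n_surface_positive: int
    n_intracellular: int
    frac_surface_positive: float  # percent of PNN-positive cells
    frac_intracellular: float  # percent of PNN-positive cells


def estimate_background(
    stack: ImageStack,
    objects: list[PNNObject],
    channel: str = "comparison",
    margin: float = 4.0,
) -> BackgroundStats:
    """Median / scaled-MAD background of ``channel`` outside every
    detected object's disc (radius + margin)."""
    img = stack[channel]
    keep = np.ones(img.shape, dtype=bool)
    for obj in objects:
        r = obj.radius + margin
        r0, r1 = int(np.floor(obj.center[0] - r)), int(np.ceil(obj.center[0] + r)) + 1
        c0, c1 = int(np.floor(obj.center[1] - r)), int(np.ceil(obj.center[1] + r)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, img.shape[0]), min(c1, img.shape[1])
        rr = np.arange(r0, r1)[:, None] - obj.center[0]
        cc = np.arange(c0, c1)[None, :] - obj.center[1]
        keep[r0:r1, c0:c1] &= np.hypot(rr, cc) > r
    bg = img[keep] if keep.any() else img.ravel()
    med = float(np.median(bg))
    sd = float(1.4826 * np.median(np.abs(bg - med)))
    if sd == 0:
        raise ValueError("zero background SD: cannot form phenotype z-scores")
    return BackgroundStats(mean=med, sd=sd)


def classify_surface(
    record: MeasurementRecord,
    background: BackgroundStats,
    params: ClassifyParams | None = None,
    channel: str = "comparison",
) -> tuple[bool, float]:
    """Surface call from the ring-mask mean of the comparison channel:
    score = (ring mean − background mean) / background SD, positive at
    ``k_surface`` or above."""
    params = params or ClassifyParams()
    score = (record.mean_intensity[channel] - background.mean) / background.sd
    return bool(score >= params.k_surface), float(score)


def detect_puncta(
    stack: ImageStack,
    obj: PNNObject,
    nucleus: NucleusCandidate | None,
    background: BackgroundStats,
    params: ClassifyParams | None = None,
    channel: str = "comparison",
) -> tuple[int, bool]:
    """Count vesicle-like puncta in the soma zone of one cell.

    The soma zone is the disc interior of the ring (pulled in by
    ``soma_margin`` so ring texture cannot leak in) minus the nucleus
    region.  Puncta are local maxima of the lightly smoothed comparison
    channel exceeding background by ``k_puncta``·SD and separated by at
    least ``puncta_min_spacing`` px.  Maxima are taken over the full
    local patch, not the masked zone alone, so a brightness gradient
    sloping up toward the ring cannot manufacture peaks at the zone
    boundary.
    """
    params = params or ClassifyParams()
    img = stack[channel]
    r_soma = obj.radius - params.soma_margin
    if r_soma <= 1.0:
        raise ValueError(f"object {obj.pnn_id}: empty soma region")
    pad = params.puncta_min_spacing + 1  # context so edge maxima are honest
    r0 = max(int(np.floor(obj.center[0] - r_soma)) - pad, 0)
    r1 = min(int(np.ceil(obj.center[0] + r_soma)) + 1 + pad, img.shape[0])
    c0 = max(int(np.floor(obj.center[1] - r_soma)) - pad, 0)
    c1 = min(int(np.ceil(obj.center[1] + r_soma)) + 1 + pad, img.shape[1])
    patch = img[r0:r1, c0:c1]
    rr = np.arange(r0, r1)[:, None] - obj.center[0]
    cc = np.arange(c0, c1)[None, :] - obj.center[1]
    soma = np.hypot(rr, cc) <= r_soma
    if nucleus is not None:
        nr = nucleus.coords[:, 0] - r0
        nc = nucleus.coords[:, 1] - c0
        ok = (nr >= 0) & (nr < patch.shape[0]) & (nc >= 0) & (nc < patch.shape[1])
        nuc_mask = np.zeros(patch.shape, dtype=bool)
        nuc_mask[nr[ok], nc[ok]] = True
        soma &= ~ndimage.binary_dilation(nuc_mask, iterations=1)
    if not soma.any():
        raise ValueError(f"object {obj.pnn_id}: empty soma region")
    smooth = ndimage.gaussian_filter(patch, params.smooth_sigma)
    thr = background.mean + params.k_puncta * background.sd
    d = 2 * params.puncta_min_spacing + 1
    yy, xx = np.mgrid[:d, :d] - params.puncta_min_spacing
    footprint = yy**2 + xx**2 <= params.puncta_min_spacing**2
    is_max = smooth >= ndimage.maximum_filter(smooth, footprint=footprint)
    count = int((is_max & soma & (smooth >= thr)).sum())
    return count, count >= params.min_puncta


def classify_all(
    stack: ImageStack,
    objects: list[PNNObject],
    nuclei: list[NucleusCandidate],
    records: list[MeasurementRecord],
    params: ClassifyParams | None = None,
    channel: str = "comparison",
) -> list[CellPhenotype]:
    """Phenotype every measured net (records and objects must be
    parallel lists from the same stack)."""
    params = params or ClassifyParams()
    background = estimate_background(stack, objects, channel=channel)
    by_id = {n.nucleus_id: n for n in nuclei}
    out: list[CellPhenotype] = []
    for obj, rec in zip(objects, records):
        surface, score = classify_surface(rec, background, params, channel)
        count, punctate = detect_puncta(
            stack, obj, by_id.get(obj.nucleus_id), background, params, channel
        )
        out.append(
            CellPhenotype(
                pnn_id=obj.pnn_id,
                surface_positive=surface,
                intracellular_punctate=punctate,
                surface_score=score,
                puncta_count=count,
            )
        )
    return out


def census(phenotypes: list[CellPhenotype]) -> PopulationFractions:
    """Percentages of PNN-positive cells carrying each phenotype.

    The denominator is the detected PNN-positive population, and is
    reported alongside the percentages.
    """
    if not phenotypes:
        raise ValueError("census needs at least one phenotype")
    n = len(phenotypes)
    n_surf = sum(p.surface_positive for p in phenotypes)
    n_intra = sum(p.intracellular_punctate for p in phenotypes)
    return PopulationFractions(
        n_pnn_cells=n,
        n_surface_positive=n_surf,
        n_intracellular=n_intra,
        frac_surface_positive=100.0 * n_surf / n,
        frac_intracellular=100.0 * n_intra / n,
    )
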