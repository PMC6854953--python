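"""Per-PNN intensity measurement and object-based colocalization.

For every validated net the mean intensity over its WFA-positive ring
mask is measured in each channel of interest — the *same* region in
every channel — and the association between the WFA and comparison
channels is summarised by the Spearman rank correlation of the pooled
per-PNN mean pairs.  The statistic is per-object, not per-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detection import PNNObject
from .io import ImageStack

__all__ = [
    "MeasurementRecord",
    "ColocalizationResult",
    "DegenerateInputError",
    "measure_intensity",
    "measure_all",
    "spearman",
    "colocalize",
]


class DegenerateInputError(ValueError):
    """A rank correlation was requested on constant input."""


@dataclass
class MeasurementRecord:
    """One row of the analysis table: a net's area and its mean
    intensity per channel over the identical ring mask."""

    pnn_id: int
    area_px: float
    area_um2: float
    mean_intensity: dict[str, float]
    image_id: str = ""
    subject_id: str = ""  # animal or dish

    def __post_init__(self) -> None:
        for name, v in self.mean_intensity.items():
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"mean intensity of {name!r} must be finite and >= 0")


@dataclass
class ColocalizationResult:
    rho: float
    n: int
    channel_pair: tuple[str, str]
    grouping: str = "pooled"
    p_value: float | None = None


def measure_intensity(
    stack: ImageStack, obj: PNNObject, channel: str, background: float = 0.0
) -> float:
    """Arithmetic mean of ``channel`` over the object's ring mask.

    No background subtraction by default; pass a per-image
    ``background`` level to subtract it (the result is floored at 0).
    """
    if obj.ring_rows is None or len(obj.ring_rows) == 0:
        raise ValueError(f"object {obj.pnn_id} has an empty ring mask")
    img = stack[channel]
    return max(float(img[obj.ring_rows, obj.ring_cols].mean()) - background, 0.0)


def measure_all(
    stack: ImageStack,
    objects: list[PNNObject],
    channels: tuple[str, ...] = ("wfa", "comparison"),
    image_id: str = "",
    subject_id: str = "",
    background: dict[str, float] | None = None,
) -> list[MeasurementRecord]:
    """One record per object, with the mean of every requested channel
    computed over the identical ring mask.  ``background`` optionally
    maps channel names to per-image levels to subtract."""
    background = background or {}
    records = []
    for obj in objects:
        means = {
            ch: measure_intensity(stack, obj, ch, background.get(ch, 0.0))
            for ch in channels
        }
        records.append(
            MeasurementRecord(
                pnn_id=obj.pnn_id,
                area_px=float(obj.ring_area_px),
                area_um2=float(obj.ring_area_px) * stack.pixel_area_um2,
                mean_intensity=means,
                image_id=image_id,
                subject_id=subject_id,
            )
        )
    return records


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Average (midrank) assignment, ties shared; 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.float64)
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(
    pairs,
    channel_pair: tuple[str, str] = ("wfa", "comparison"),
    permutation_p: bool = False,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ColocalizationResult:
    """Spearman rank correlation: Pearson correlation of average-
    assigned ranks, exact under ties.

    Raises on fewer than three pairs or on a constant variable (a
    degenerate correlation is an error, not a silent zero).  A
    permutation p-value is attached only when requested.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) sequence")
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 pairs for a rank correlation, got {n}")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("rank correlation undefined for constant input")
    rx, ry = _average_ranks(x), _average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    p = None
    if permutation_p:
        rng = np.random.default_rng(seed)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            r = float((rxc[perm] * ryc).sum() / denom)
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return ColocalizationResult(rho=rho, n=n, channel_pair=channel_pair, p_value=p)


def colocalize(
    records: list[MeasurementRecord],
    channel_a: str = "wfa",
    channel_b: str = "comparison",
    grouping: str = "pooled",
    **spearman_kwargs,
) -> ColocalizationResult:
    """Spearman correlation of the per-PNN (mean_a, mean_b) pairs.

    The default pools all records into one coefficient over all
    subjects; for a per-subject design, filter the records upstream and
    call this once per subject.
    """
    if grouping != "pooled":
        raise ValueError(f"unknown grouping {grouping!r}")
    pairs = [
        (r.mean_intensity[channel_a], r.mean_intensity[channel_b]) for r in records
    ]
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 records, got {len(pairs)}")
    res = spearman(pairs, channel_pair=(channel_a, channel_b), **spearman_kwargs)
    res.grouping = grouping
    return res
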