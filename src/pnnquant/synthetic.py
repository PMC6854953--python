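"""Synthetic multi-channel fluorescence scenes with known ground truth.

The generator emulates single-plane confocal images of cortical tissue
or culture in four named channels:

``nuclear``
    Diffuse Hoechst-like signal: one soft disc per cell.
``wfa``
    The PNN detection channel.  Cells carrying a perineuronal net
    render a punctate annulus (a dot field restricted to the ring,
    blurred by a small Gaussian) centred on the nucleus, normalised so
    the mean intensity over the true geometric ring mask equals the
    cell's ``wfa_level`` exactly in the noiseless rendering.
``comparison``
    The tagged-protein channel (myc- or his-tag in the motivating
    experiments).  Surface-positive cells re-use the *same* ring
    texture scaled to ``comparison_surface_level``, so the tag sits on
    the net itself; intracellular-punctate cells additionally render
    vesicle-like Gaussian puncta in the soma between nucleus and ring.
``pv``
    Parvalbumin-like soma fill for the ``is_pv`` subset.

Per-PNN intensity levels of the two coupled channels are drawn through
a Gaussian copula so that the population Spearman correlation among
surface-positive PNN cells equals ``coupling_rho``: correlated standard
normals at the Pearson value 2·sin(π·ρ_s/6) are pushed through strictly
monotone marginal maps, which preserves ranks and hence the target
Spearman regardless of the marginal intensity distributions.

Everything is driven by one ``numpy`` Generator seeded from the config,
so identical configs give bit-identical images and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .io import ImageStack

__all__ = [
    "CellSpec",
    "NoiseModel",
    "IntensityLevels",
    "GeneratorConfig",
    "GroundTruth",
    "PlacementError",
    "draw_cell_specs",
    "generate_scene",
    "write_ground_truth",
    "read_ground_truth",
    "true_ring_mask",
    "add_nucleus",
    "add_ring_texture",
    "add_puncta",
    "invivo_config",
    "culture_config",
]

CHANNELS = ("nuclear", "wfa", "comparison", "pv")


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested spacing."""


@dataclass
class CellSpec:
    """Ground-truth description of one simulated cell."""

    cell_id: int
    center: tuple[float, float]  # (row, col), 0-based, origin top-left
    nucleus_radius: float  # px
    has_pnn: bool
    pnn_radius: float  # px, > nucleus_radius when has_pnn
    pnn_thickness: float  # px, half-width of the annulus
    wfa_level: float  # true mean ring intensity, [0, 1] scale
    comparison_surface_level: float  # 0 unless surface_positive
    surface_positive: bool
    intracellular_punctate: bool
    n_puncta: int
    is_pv: bool

    def __post_init__(self) -> None:
        if self.has_pnn and not self.pnn_radius > self.nucleus_radius:
            raise ValueError("pnn_radius must exceed nucleus_radius for PNN cells")
        if not self.surface_positive and self.comparison_surface_level != 0:
            raise ValueError("comparison_surface_level must be 0 for surface-negative cells")
        if not self.intracellular_punctate and self.n_puncta != 0:
            raise ValueError("n_puncta must be 0 for non-punctate cells")


@dataclass
class NoiseModel:
    """Additive background model applied after rendering.

    sigma: Gaussian read-noise SD; baseline: constant background offset;
    shot_noise: apply Poisson resampling at ``photons_per_unit`` photons
    for an intensity of 1.0 before the additive terms.
    """

    sigma: float = 0.01
    baseline: float = 0.05
    shot_noise: bool = False
    photons_per_unit: float = 5000.0


@dataclass
class IntensityLevels:
    """Marginal intensity distributions per channel ([0, 1] scale).

    Ring levels are uniform over the given (lo, hi) ranges; the copula
    only needs the maps to be strictly monotone.
    """

    wfa_range: tuple[float, float] = (0.30, 0.75)
    comparison_range: tuple[float, float] = (0.25, 0.65)
    nuclear_level: float = 0.60
    pv_level: float = 0.50
    puncta_amplitude: float = 0.50


@dataclass
class GeneratorConfig:
    """Scene parameters.  Defaults mirror the motivating acquisitions:
    1024 × 1024 single planes, a rank coupling of 0.816 between the WFA
    and comparison ring intensities, and surface-positive /
    intracellular-punctate fractions of 66% / 29% among PNN cells.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.5  # micrometres / pixel
    n_cells: int = 80
    frac_pnn: float = 0.60
    frac_surface_positive: float = 0.66
    frac_intracellular: float = 0.29
    frac_pv: float = 0.30
    coupling_rho: float = 0.816
    intensity: IntensityLevels = field(default_factory=IntensityLevels)
    noise: NoiseModel = field(default_factory=NoiseModel)
    nucleus_radius_range: tuple[float, float] = (3.5, 4.5)
    pnn_radius_range: tuple[float, float] = (16.0, 22.0)
    pnn_thickness: float = 2.5
    n_puncta_range: tuple[int, int] = (4, 8)
    puncta_sigma: float = 1.2  # px, Gaussian SD of one vesicle
    puncta_spacing: float = 3.5  # px, min distance between puncta
    ring_dot_spacing: float = 2.5  # px, Poisson-disc spacing of ring dots
    puncta_size: float = 1.2  # alias kept for config files; see puncta_sigma
    min_center_spacing: float | None = None  # derived when None
    exact_count: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.puncta_size = self.puncta_sigma
        if self.min_center_spacing is None:
            # guarantees non-overlapping rings incl. texture blur margin
            self.min_center_spacing = 2.0 * (
                self.pnn_radius_range[1] + self.pnn_thickness
            ) + 3.0

    def validate(self) -> None:
        rows, cols = self.image_shape
        if not (rows > 0 and cols > 0):
            raise ValueError("image_shape must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("frac_pnn", "frac_surface_positive", "frac_intracellular", "frac_pv"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (np.isfinite(self.coupling_rho) and -1.0 <= self.coupling_rho <= 1.0):
            raise ValueError(f"coupling_rho must lie in [-1, 1], got {self.coupling_rho}")
        for name in ("pixel_size", "pnn_thickness", "puncta_sigma", "min_center_spacing"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        for name in ("nucleus_radius_range", "pnn_radius_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo <= hi):
                raise ValueError(f"{name} must be an increasing positive pair")
        if self.pnn_radius_range[0] <= self.nucleus_radius_range[1]:
            raise ValueError("pnn radii must exceed nucleus radii")
        if self.n_puncta_range[0] < 1 or self.n_puncta_range[0] > self.n_puncta_range[1]:
            raise ValueError("n_puncta_range must be an increasing pair >= 1")
        if not np.isfinite(self.noise.sigma) or self.noise.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class GroundTruth:
    """Per-cell truth emitted alongside each scene."""

    cells: list[CellSpec]
    config_echo: GeneratorConfig
    true_ring_means: dict[int, dict[str, float]]

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell_ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "cell_id", "row", "col", "nucleus_radius", "has_pnn", "pnn_radius",
            "pnn_thickness", "wfa_level", "comparison_surface_level",
            "surface_positive", "intracellular_punctate", "n_puncta", "is_pv",
        ]
        rows = []
        for c in self.cells:
            d = dataclasses.asdict(c)
            d["row"], d["col"] = d.pop("center")
            rows.append(d)
        return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)

    @property
    def pnn_cells(self) -> list[CellSpec]:
        return [c for c in self.cells if c.has_pnn]


# ---------------------------------------------------------------------------
# sampling


def _spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of the latent normals that induces a given
    population Spearman for a Gaussian copula: ρ_p = 2·sin(π·ρ_s/6)."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _place_centers(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    rows, cols = config.image_shape
    margin = config.pnn_radius_range[1] + config.pnn_thickness + 3.0
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        if config.n_cells > 0:
            raise PlacementError(
                f"image {config.image_shape} too small for any cell at margin {margin:.1f}"
            )
        return np.empty((0, 2))
    centers: list[tuple[float, float]] = []
    spacing = config.min_center_spacing
    spacing2 = spacing**2
    # spatial hash: only neighbouring buckets need a distance check
    buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}
    max_tries = 300 * max(config.n_cells, 1)
    tries = 0
    while len(centers) < config.n_cells and tries < max_tries:
        tries += 1
        r = rng.uniform(margin, rows - margin)
        c = rng.uniform(margin, cols - margin)
        key = (int(r // spacing), int(c // spacing))
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for r0, c0 in buckets.get((key[0] + dr, key[1] + dc), ()):
                    if (r - r0) ** 2 + (c - c0) ** 2 < spacing2:
                        ok = False
        if ok:
            centers.append((r, c))
            buckets.setdefault(key, []).append((r, c))
    if len(centers) < config.n_cells:
        raise PlacementError(
            f"placed only {len(centers)} of {config.n_cells} cells at "
            f"min_center_spacing={config.min_center_spacing:.1f} after {max_tries} tries"
        )
    return np.asarray(centers)


def _boolean_draw(n: int, frac: float, exact: bool, rng: np.random.Generator) -> np.ndarray:
    """n boolean labels: Bernoulli(frac), or exactly round(frac*n) positives."""
    if n == 0:
        return np.zeros(0, dtype=bool)
    if exact:
        k = int(round(frac * n))
        out = np.zeros(n, dtype=bool)
        out[rng.permutation(n)[:k]] = True
        return out
    return rng.random(n) < frac


def draw_cell_specs(config: GeneratorConfig, rng: np.random.Generator | None = None) -> list[CellSpec]:
    """Sample the per-cell ground truth (positions, phenotypes, levels)
    without rendering anything.  ``generate_scene`` calls this first and
    then renders; calling it directly is useful for population-level
    checks at cell counts too large to paint.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    centers = _place_centers(config, rng)
    n = len(centers)

    has_pnn = _boolean_draw(n, config.frac_pnn, config.exact_count, rng)
    n_pnn = int(has_pnn.sum())
    surface_among_pnn = _boolean_draw(n_pnn, config.frac_surface_positive, config.exact_count, rng)
    punctate_among_pnn = _boolean_draw(n_pnn, config.frac_intracellular, config.exact_count, rng)
    is_pv = _boolean_draw(n, config.frac_pv, config.exact_count, rng)

    nucleus_r = rng.uniform(*config.nucleus_radius_range, size=n)
    pnn_r = rng.uniform(*config.pnn_radius_range, size=n)

    # Gaussian copula: correlated normals -> uniforms -> intensity ranges
    rho_p = _spearman_to_pearson(config.coupling_rho)
    z1 = rng.standard_normal(n)
    z2 = rho_p * z1 + np.sqrt(max(0.0, 1.0 - rho_p**2)) * rng.standard_normal(n)
    if config.coupling_rho == 1.0:
        z2 = z1.copy()
    elif config.coupling_rho == -1.0:
        z2 = -z1
    u1, u2 = ndtr(z1), ndtr(z2)
    wfa_lo, wfa_hi = config.intensity.wfa_range
    cmp_lo, cmp_hi = config.intensity.comparison_range
    wfa_levels = wfa_lo + (wfa_hi - wfa_lo) * u1
    cmp_levels = cmp_lo + (cmp_hi - cmp_lo) * u2

    n_puncta_draw = rng.integers(
        config.n_puncta_range[0], config.n_puncta_range[1] + 1, size=n
    )

    cells: list[CellSpec] = []
    i_pnn = 0
    for i in range(n):
        pnn = bool(has_pnn[i])
        if pnn:
            surface = bool(surface_among_pnn[i_pnn])
            punctate = bool(punctate_among_pnn[i_pnn])
            i_pnn += 1
        else:
            surface = punctate = False
        cells.append(
            CellSpec(
                cell_id=i,
                center=(float(centers[i, 0]), float(centers[i, 1])),
                nucleus_radius=float(nucleus_r[i]),
                has_pnn=pnn,
                pnn_radius=float(pnn_r[i]),
                pnn_thickness=float(config.pnn_thickness),
                wfa_level=float(wfa_levels[i]) if pnn else 0.0,
                comparison_surface_level=float(cmp_levels[i]) if surface else 0.0,
                surface_positive=surface,
                intracellular_punctate=punctate,
                n_puncta=int(n_puncta_draw[i]) if punctate else 0,
                is_pv=bool(is_pv[i]),
            )
        )
    return cells


# ---------------------------------------------------------------------------
# rendering primitives


def _patch_view(img: np.ndarray, center: tuple[float, float], half: int):
    """A square view of img around center, its distance-to-center grid,
    and the (row, col) origin of the view in image coordinates."""
    rows, cols = img.shape
    r0 = int(np.floor(center[0])) - half
    c0 = int(np.floor(center[1])) - half
    r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r1, rows), min(c1, cols)
    rr = np.arange(rs, re)[:, None] - center[0]
    cc = np.arange(cs, ce)[None, :] - center[1]
    dist = np.hypot(rr, cc)
    return img[rs:re, cs:ce], dist, (rs, cs)


def true_ring_mask(
    shape: tuple[int, int], center: tuple[float, float], radius: float, thickness: float
) -> np.ndarray:
    """Boolean mask of the geometric annulus |d - radius| <= thickness."""
    rows, cols = shape
    rr = np.arange(rows)[:, None] - center[0]
    cc = np.arange(cols)[None, :] - center[1]
    dist = np.hypot(rr, cc)
    return np.abs(dist - radius) <= thickness


def add_nucleus(img: np.ndarray, center: tuple[float, float], radius: float, level: float) -> None:
    """Paint a soft-edged disc (~1 px roll-off) in place."""
    patch, dist, _ = _patch_view(img, center, int(np.ceil(radius)) + 3)
    patch += level * np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _dart_throw_annulus(
    rng: np.random.Generator,
    r_in: float,
    r_out: float,
    spacing: float,
    n_target: int | None,
    max_tries: int,
) -> np.ndarray:
    """Poisson-disc-like dart throwing inside an annulus centred at 0.

    Stops at ``n_target`` accepted points when given, else at max_tries.
    Returns an (k, 2) array of (row, col) offsets.
    """
    pts: list[tuple[float, float]] = []
    sp2 = spacing**2
    for _ in range(max_tries):
        if n_target is not None and len(pts) >= n_target:
            break
        rad = np.sqrt(rng.uniform(r_in**2, r_out**2))
        ang = rng.uniform(0.0, 2.0 * np.pi)
        p = (rad * np.cos(ang), rad * np.sin(ang))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= sp2 for q in pts):
            pts.append(p)
    return np.asarray(pts) if pts else np.empty((0, 2))


def add_ring_texture(
    img: np.ndarray,
    center: tuple[float, float],
    radius: float,
    thickness: float,
    level: float,
    rng: np.random.Generator,
    dot_spacing: float = 2.5,
    dot_sigma: float = 1.2,
    precomputed: np.ndarray | None = None,
) -> np.ndarray:
    """Paint a punctate annulus whose mean over the true ring mask is
    exactly ``level`` (before noise).

    Texture = a soft annular base plus a Poisson-disc dot field blurred
    by a small Gaussian, then rescaled on the true mask.  Returns the
    normalised local texture patch so a second channel can re-use the
    identical texture at a different level (``precomputed``).
    """
    half = int(np.ceil(radius + thickness)) + 4
    patch, dist, origin = _patch_view(img, center, half)
    if precomputed is None:
        inner, outer = radius - thickness, radius + thickness
        # soft annular base plus a moderate-contrast dot field: keeps the
        # punctate look while the normalised texture peaks stay low enough
        # that level * texture fits the [0, 1] dynamic range
        base = np.clip(outer + 0.5 - dist, 0.0, 1.0) * np.clip(dist - inner + 0.5, 0.0, 1.0)
        dots = np.zeros_like(patch)
        n_dots = max(4, int(2.0 * np.pi * radius * 2 * thickness / dot_spacing**2))
        pts = _dart_throw_annulus(rng, inner, outer, dot_spacing, n_dots, 60 * n_dots)
        # impulse at nearest pixel; the blur spreads it into a dot
        for p in pts:
            i = int(round(p[0] + center[0])) - origin[0]
            j = int(round(p[1] + center[1])) - origin[1]
            if 0 <= i < patch.shape[0] and 0 <= j < patch.shape[1]:
                dots[i, j] += 1.0
        texture = base + 0.6 * ndimage.gaussian_filter(dots, dot_sigma) * (2.0 * np.pi * dot_sigma**2)
        mask = np.abs(dist - radius) <= thickness
        m = texture[mask].mean() if mask.any() else 1.0
        texture = texture / m if m > 0 else texture
    else:
        texture = precomputed
    patch += level * texture
    return texture


def add_puncta(
    img: np.ndarray,
    center: tuple[float, float],
    r_in: float,
    r_out: float,
    n: int,
    rng: np.random.Generator,
    amplitude: float,
    sigma: float,
    spacing: float,
) -> int:
    """Paint up to ``n`` vesicle-like Gaussian puncta in the annular
    soma zone [r_in, r_out]; returns the number actually placed."""
    if r_out <= r_in or n <= 0:
        return 0
    pts = _dart_throw_annulus(rng, r_in, r_out, spacing, n, 400 * n)
    half = int(np.ceil(r_out)) + 4
    patch, _, origin = _patch_view(img, center, half)
    rr = np.arange(patch.shape[0])[:, None] + origin[0]
    cc = np.arange(patch.shape[1])[None, :] + origin[1]
    for p in pts:
        pr, pc = p[0] + center[0], p[1] + center[1]
        patch += amplitude * np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * sigma**2))
    return len(pts)


# ---------------------------------------------------------------------------
# scene assembly


def generate_scene(config: GeneratorConfig) -> tuple[ImageStack, GroundTruth]:
    """Render one scene and its ground truth.

    Fixed config (including its seed) gives bit-identical output.  The
    soma zone available to intracellular puncta is the annulus between
    the nucleus edge and a safety margin inside the PNN ring, so puncta
    never blend into the ring texture; if the zone cannot hold the
    drawn count at the requested spacing the truth records the number
    actually rendered.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = draw_cell_specs(config, rng)

    rows, cols = config.image_shape
    imgs = {name: np.zeros((rows, cols), dtype=np.float64) for name in CHANNELS}
    lv = config.intensity

    for cell in cells:
        add_nucleus(imgs["nuclear"], cell.center, cell.nucleus_radius, lv.nuclear_level)
        if cell.is_pv:
            soma_r = cell.pnn_radius - cell.pnn_thickness - 1.0 if cell.has_pnn else 2.2 * cell.nucleus_radius
            add_nucleus(imgs["pv"], cell.center, soma_r, lv.pv_level)
        if cell.has_pnn:
            texture = add_ring_texture(
                imgs["wfa"], cell.center, cell.pnn_radius, cell.pnn_thickness,
                cell.wfa_level, rng,
                dot_spacing=config.ring_dot_spacing, dot_sigma=config.puncta_sigma,
            )
            if cell.surface_positive:
                add_ring_texture(
                    imgs["comparison"], cell.center, cell.pnn_radius, cell.pnn_thickness,
                    cell.comparison_surface_level, rng, precomputed=texture,
                )
            if cell.intracellular_punctate:
                placed = add_puncta(
                    imgs["comparison"], cell.center,
                    r_in=cell.nucleus_radius + 1.5,
                    r_out=cell.pnn_radius - cell.pnn_thickness - 5.5,
                    n=cell.n_puncta, rng=rng,
                    amplitude=lv.puncta_amplitude, sigma=config.puncta_sigma,
                    spacing=config.puncta_spacing,
                )
                if placed != cell.n_puncta:
                    cell.n_puncta = placed
                    if placed == 0:
                        cell.intracellular_punctate = False

    noise = config.noise
    for name in CHANNELS:
        img = imgs[name]
        if noise.shot_noise:
            img = rng.poisson(np.clip(img, 0, None) * noise.photons_per_unit) / noise.photons_per_unit
        img = img + noise.baseline
        if noise.sigma > 0:
            img = img + noise.sigma * rng.standard_normal(img.shape)
        imgs[name] = np.clip(img, 0.0, 1.0)

    stack = ImageStack(channels=imgs, pixel_size=config.pixel_size)
    true_means = {
        c.cell_id: {"wfa": c.wfa_level, "comparison": c.comparison_surface_level}
        for c in cells if c.has_pnn
    }
    gt = GroundTruth(cells=cells, config_echo=config, true_ring_means=true_means)
    return stack, gt


# ---------------------------------------------------------------------------
# truth table round trip


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Write the truth table as CSV (one row per cell, stable column
    order) with the generator config and true ring means in a JSON
    sidecar, so a read round-trips to an equal GroundTruth."""
    path = Path(path)
    gt.to_frame().to_csv(path, index=False, float_format="%.17g")
    meta = {
        "config": dataclasses.asdict(gt.config_echo),
        "true_ring_means": {str(k): v for k, v in gt.true_ring_means.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, sort_keys=True))
    return path


def _config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    d["intensity"] = IntensityLevels(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["intensity"].items()
        }
    )
    d["noise"] = NoiseModel(**d["noise"])
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return GeneratorConfig(**d)


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cells = [
        CellSpec(
            cell_id=int(r.cell_id),
            center=(float(r.row), float(r.col)),
            nucleus_radius=float(r.nucleus_radius),
            has_pnn=bool(r.has_pnn),
            pnn_radius=float(r.pnn_radius),
            pnn_thickness=float(r.pnn_thickness),
            wfa_level=float(r.wfa_level),
            comparison_surface_level=float(r.comparison_surface_level),
            surface_positive=bool(r.surface_positive),
            intracellular_punctate=bool(r.intracellular_punctate),
            n_puncta=int(r.n_puncta),
            is_pv=bool(r.is_pv),
        )
        for r in df.itertuples()
    ]
    return GroundTruth(
        cells=cells,
        config_echo=_config_from_dict(meta["config"]),
        true_ring_means={int(k): v for k, v in meta["true_ring_means"].items()},
    )


# ---------------------------------------------------------------------------
# presets


def invivo_config(**overrides) -> GeneratorConfig:
    """Cortical-section preset: the defaults (coupling 0.816, 66% / 29%
    phenotype fractions among PNN cells)."""
    return GeneratorConfig(**overrides)


def culture_config(
    treated: bool = False,
    radius_scale: float = 1.15,
    intensity_scale: float = 1.2,
    **overrides,
) -> GeneratorConfig:
    """Neuronal-culture preset at the stage where nets are still
    forming: fewer, dimmer rings; every ring-bearing cell is PV.  The
    treated variant has more, larger and brighter rings (the direction
    of the exogenous-pentraxin effect)."""
    base = dict(
        n_cells=60,
        frac_pnn=0.40 if treated else 0.30,
        frac_surface_positive=1.0,
        frac_intracellular=0.0,
        frac_pv=1.0,
        coupling_rho=0.7,
    )
    base.update(overrides)
    cfg = GeneratorConfig(**base)
    if treated:
        lo, hi = cfg.pnn_radius_range
        cfg.pnn_radius_range = (lo * radius_scale, hi * radius_scale)
        wlo, whi = cfg.intensity.wfa_range
        cfg.intensity.wfa_range = (min(wlo * intensity_scale, 0.95), min(whi * intensity_scale, 0.95))
        cfg.min_center_spacing = 2.0 * (cfg.pnn_radius_range[1] + cfg.pnn_thickness) + 3.0
    return cfg
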