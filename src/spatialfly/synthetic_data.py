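"""Ground-truth scene generator.

Builds multi-region tissue layouts (rectangular regions, circular nuclei)
with per-gene spatial point patterns — uniform, nucleus-enriched,
nucleus-depleted, striped, terminal-enriched, and region-boundary
(apical/basal) — and emits a :class:`~spatialfly.core_io.SpotTable` with
matching nucleus and region masks, so every downstream stage can be tested
without external data.

All randomness flows through a single ``numpy.random.default_rng(seed)``
stream consumed in declared gene order; identical (spec, seed) pairs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import GenePanel, RasterMask, SpotTable

__all__ = [
    "Region",
    "Nucleus",
    "GeneSpec",
    "SceneSpec",
    "SyntheticScene",
    "simulate_scene",
    "paper_like_body_scene",
]

PATTERNS = (
    "uniform",
    "nucleus_enriched",
    "nucleus_depleted",
    "striped",
    "terminal_enriched",
    "boundary_apical",
    "boundary_basal",
)

#: default standard deviation of the isotropic localization jitter, in µm
DEFAULT_LOCALIZATION_SIGMA = 0.14


class SceneSpecError(ValueError):
    """Raised when a scene specification is internally inconsistent."""


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangular tissue region, world µm coordinates."""

    name: str
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise SceneSpecError(f"region {self.name!r} has non-positive extent")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    def sample_uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.uniform(self.x0, self.x1, n)
        y = rng.uniform(self.y0, self.y1, n)
        return np.column_stack([x, y])


@dataclass(frozen=True)
class Nucleus:
    x: float
    y: float
    radius: float
    region: str


@dataclass(frozen=True)
class GeneSpec:
    """Generative recipe for one gene.

    ``params`` (all lengths in µm):
      nucleus_enriched: sigma (Gaussian scale around nucleus centers)
      nucleus_depleted: well_radius, well_depth in [0, 1) (acceptance factor
          inside the well)
      striped: period (> 0), phase (radians), axis ('x' or 'y')
      terminal_enriched: decay_scale (> 0), end ('low' or 'high' coordinate
          along axis), axis
      boundary_apical / boundary_basal: decay_scale; apical decays from the
          low-x region edge, basal from the high-x edge
    """

    name: str
    regions: tuple[str, ...]
    pattern: str
    expected_spots: float
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise SceneSpecError(f"unknown pattern {self.pattern!r}")
        if self.expected_spots < 0:
            raise SceneSpecError("expected_spots must be >= 0")
        if self.pattern == "striped" and not float(self.params.get("period", 10.0)) > 0:
            raise SceneSpecError("stripe period must be > 0")
        for key in ("sigma", "decay_scale"):
            if key in self.params and not float(self.params[key]) > 0:
                raise SceneSpecError(f"{key} must be > 0")


@dataclass(frozen=True)
class SceneSpec:
    width: float
    height: float
    regions: tuple[Region, ...]
    nuclei: tuple[Nucleus, ...]
    genes: tuple[GeneSpec, ...]
    pixel_size: float = 0.138
    localization_sigma: float = DEFAULT_LOCALIZATION_SIGMA
    background_spots: float = 0.0  # mean uniform false-positive spots per gene

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(names) != len(set(names)):
            raise SceneSpecError("region names must be unique")
        by_name = {r.name: r for r in self.regions}
        for r in self.regions:
            if not (0 <= r.x0 and r.x1 <= self.width and 0 <= r.y0 and r.y1 <= self.height):
                raise SceneSpecError(f"region {r.name!r} outside scene extent")
        for nuc in self.nuclei:
            region = by_name.get(nuc.region)
            if region is None:
                raise SceneSpecError(f"nucleus references unknown region {nuc.region!r}")
            if not region.contains(nuc.x, nuc.y):
                raise SceneSpecError(f"nucleus at ({nuc.x}, {nuc.y}) outside {nuc.region!r}")
        for g in self.genes:
            for rname in g.regions:
                if rname not in by_name:
                    raise SceneSpecError(f"gene {g.name!r} references unknown region {rname!r}")
            if g.pattern in ("nucleus_enriched", "nucleus_depleted"):
                if not any(n.region in g.regions for n in self.nuclei):
                    raise SceneSpecError(
                        f"gene {g.name!r} uses a nucleus-dependent pattern but its "
                        f"regions contain no nuclei"
                    )

    @property
    def panel(self) -> GenePanel:
        return GenePanel(
            tuple(g.name for g in self.genes),
            metadata={g.name: {"pattern": g.pattern, "regions": list(g.regions)} for g in self.genes},
        )

    def region_by_name(self, name: str) -> Region:
        return {r.name: r for r in self.regions}[name]

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            width=float(raw["width"]),
            height=float(raw["height"]),
            regions=tuple(Region(**r) for r in raw.get("regions", [])),
            nuclei=tuple(Nucleus(**n) for n in raw.get("nuclei", [])),
            genes=tuple(
                GeneSpec(
                    name=g["name"],
                    regions=tuple(g["regions"]),
                    pattern=g["pattern"],
                    expected_spots=float(g["expected_spots"]),
                    params=g.get("params", {}),
                )
                for g in raw.get("genes", [])
            ),
            pixel_size=float(raw.get("pixel_size", 0.138)),
            localization_sigma=float(raw.get("localization_sigma", DEFAULT_LOCALIZATION_SIGMA)),
            background_spots=float(raw.get("background_spots", 0.0)),
        )


@dataclass
class SyntheticScene:
    """A realized scene: the spec, its seed, and per-gene ground truth."""

    spec: SceneSpec
    seed: int
    spots: SpotTable
    nucleus_mask: RasterMask
    region_masks: dict[str, RasterMask]
    gene_counts: dict[str, int]

    @property
    def panel(self) -> GenePanel:
        return self.spec.panel

    def region_of_gene(self, gene: str) -> tuple[str, ...]:
        return {g.name: g.regions for g in self.spec.genes}[gene]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _pick_regions(rng: np.random.Generator, regions: Sequence[Region], n: int) -> np.ndarray:
    areas = np.array([r.area for r in regions], dtype=float)
    return rng.choice(len(regions), size=n, p=areas / areas.sum())


def _sample_uniform(rng, regions, n):
    idx = _pick_regions(rng, regions, n)
    pts = np.empty((n, 2))
    for k, region in enumerate(regions):
        sel = idx == k
        pts[sel] = region.sample_uniform(rng, int(sel.sum()))
    return pts


def _sample_nucleus_enriched(rng, regions, nuclei, n, sigma):
    centers = np.array([[nu.x, nu.y] for nu in nuclei])
    pts = np.empty((n, 2))
    filled = 0
    # rejection against the region union keeps the Gaussian mixture truncated
    while filled < n:
        m = max(n - filled, 64)
        which = rng.integers(0, len(nuclei), m)
        cand = centers[which] + rng.normal(0.0, sigma, (m, 2))
        ok = np.zeros(m, dtype=bool)
        for region in regions:
            ok |= region.contains(cand[:, 0], cand[:, 1])
        kept = cand[ok][: n - filled]
        pts[filled : filled + len(kept)] = kept
        filled += len(kept)
    return pts


def _nearest_nucleus_distance(pts: np.ndarray, nuclei) -> np.ndarray:
    centers = np.array([[nu.x, nu.y] for nu in nuclei])
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1))


def _rejection_sample(rng, regions, n, accept_prob):
    """Sample n points uniform-over-regions thinned by accept_prob(pts) in [0, 1]."""
    pts = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 128)
        cand = _sample_uniform(rng, regions, m)
        p = accept_prob(cand)
        keep = rng.uniform(0.0, 1.0, m) < p
        kept = cand[keep][: n - filled]
        pts[filled : filled + len(kept)] = kept
        filled += len(kept)
    return pts


def _sample_gene(rng: np.random.Generator, spec: SceneSpec, gene: GeneSpec, n: int) -> np.ndarray:
    regions = [spec.region_by_name(r) for r in gene.regions]
    nuclei = [nu for nu in spec.nuclei if nu.region in gene.regions]
    params = gene.params

    if gene.pattern == "uniform":
        return _sample_uniform(rng, regions, n)

    if gene.pattern == "nucleus_enriched":
        sigma = float(params.get("sigma", 1.0))
        return _sample_nucleus_enriched(rng, regions, nuclei, n, sigma)

    if gene.pattern == "nucleus_depleted":
        well_radius = float(params.get("well_radius", 5.0))
        well_depth = float(params.get("well_depth", 0.05))
        if not 0 <= well_depth < 1:
            raise SceneSpecError("well_depth must be in [0, 1)")

        def accept(pts):
            d = _nearest_nucleus_distance(pts, nuclei)
            return np.where(d < well_radius, well_depth, 1.0)

        return _rejection_sample(rng, regions, n, accept)

    if gene.pattern == "striped":
        period = float(params.get("period", 10.0))
        phase = float(params.get("phase", 0.0))
        axis = 0 if params.get("axis", "x") == "x" else 1

        def accept(pts):
            return 0.5 * (1.0 + np.cos(2 * np.pi * pts[:, axis] / period + phase))

        return _rejection_sample(rng, regions, n, accept)

    if gene.pattern == "terminal_enriched":
        scale = float(params.get("decay_scale", 10.0))
        axis = 0 if params.get("axis", "x") == "x" else 1
        end = params.get("end", "low")
        lo = min(r.x0 if axis == 0 else r.y0 for r in regions)
        hi = max(r.x1 if axis == 0 else r.y1 for r in regions)

        def accept(pts):
            u = pts[:, axis]
            dist = (u - lo) if end == "low" else (hi - u)
            return np.exp(-dist / scale)

        return _rejection_sample(rng, regions, n, accept)

    # boundary_apical / boundary_basal: exponential decay from one x edge
    scale = float(params.get("decay_scale", 3.0))
    lo = min(r.x0 for r in regions)
    hi = max(r.x1 for r in regions)
    apical = gene.pattern == "boundary_apical"

    def accept(pts):
        dist = (pts[:, 0] - lo) if apical else (hi - pts[:, 0])
        return np.exp(-dist / scale)

    return _rejection_sample(rng, regions, n, accept)


# ---------------------------------------------------------------------------
# mask rendering
# ---------------------------------------------------------------------------


def _blank_raster(spec: SceneSpec) -> np.ndarray:
    shape = (
        int(np.ceil(spec.height / spec.pixel_size)),
        int(np.ceil(spec.width / spec.pixel_size)),
    )
    return np.zeros(shape, dtype=bool)


def _render_region_mask(spec: SceneSpec, region: Region) -> RasterMask:
    raster = _blank_raster(spec)
    s = spec.pixel_size
    r0 = int(np.floor(region.y0 / s))
    r1 = int(np.ceil(region.y1 / s))
    c0 = int(np.floor(region.x0 / s))
    c1 = int(np.ceil(region.x1 / s))
    raster[r0:r1, c0:c1] = True
    return RasterMask(raster, pixel_size=s)


def _render_nucleus_mask(spec: SceneSpec) -> RasterMask:
    raster = _blank_raster(spec)
    s = spec.pixel_size
    rows = (np.arange(raster.shape[0]) + 0.5) * s
    cols = (np.arange(raster.shape[1]) + 0.5) * s
    for nu in spec.nuclei:
        r0 = max(int((nu.y - nu.radius) / s) - 1, 0)
        r1 = min(int((nu.y + nu.radius) / s) + 2, raster.shape[0])
        c0 = max(int((nu.x - nu.radius) / s) - 1, 0)
        c1 = min(int((nu.x + nu.radius) / s) + 2, raster.shape[1])
        dy = rows[r0:r1, None] - nu.y
        dx = cols[None, c0:c1] - nu.x
        raster[r0:r1, c0:c1] |= dx * dx + dy * dy <= nu.radius**2
    return RasterMask(raster, pixel_size=s)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


def simulate_scene(
    spec: SceneSpec, seed: int, *, sample: str = "sample0"
) -> SyntheticScene:
    """Realize a scene: Poisson counts per gene, pattern-density positions,
    localization jitter, optional uniform background, rendered masks."""
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    gene_counts: dict[str, int] = {}

    for gene in spec.genes:  # documented order: as declared in the spec
        n = int(rng.poisson(gene.expected_spots))
        gene_counts[gene.name] = n
        pts = _sample_gene(rng, spec, gene, n) if n else np.empty((0, 2))
        if spec.localization_sigma > 0 and n:
            pts = pts + rng.normal(0.0, spec.localization_sigma, pts.shape)
        frames.append(pd.DataFrame({"gene": gene.name, "x": pts[:, 0], "y": pts[:, 1]}))
        if spec.background_spots > 0:
            nb = int(rng.poisson(spec.background_spots))
            if nb:
                bx = rng.uniform(0, spec.width, nb)
                by = rng.uniform(0, spec.height, nb)
                frames.append(pd.DataFrame({"gene": gene.name, "x": bx, "y": by}))

    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["gene", "x", "y"])
    )
    df["sample"] = sample
    spots = SpotTable(df, spec.panel)

    return SyntheticScene(
        spec=spec,
        seed=seed,
        spots=spots,
        nucleus_mask=_render_nucleus_mask(spec),
        region_masks={r.name: _render_region_mask(spec, r) for r in spec.regions},
        gene_counts=gene_counts,
    )


def paper_like_body_scene(seed: int = 0, *, spots_scale: float = 1.0) -> SyntheticScene:
    """Canned multi-region body section used as the standard fixture.

    Six regions, each with at least one exclusive marker gene; the muscle
    region carries a nucleus-enriched gene, a nucleus-depleted gene and two
    complementary striped genes (phases half a period apart); the gut region
    carries an apical/basal boundary pair. ``spots_scale`` rescales every
    gene's expected spot count.
    """
    regions = (
        Region("muscle", 10, 10, 130, 90),
        Region("brain", 150, 10, 230, 70),
        Region("gut", 150, 90, 230, 150),
        Region("fat", 10, 110, 110, 160),
        Region("epithelia", 240, 10, 290, 160),
        Region("heart", 120, 120, 140, 160),
    )
    nuclei = []
    for gx in range(6):
        for gy in range(4):
            nuclei.append(Nucleus(22.0 + 20.0 * gx, 20.0 + 18.0 * gy, 2.5, "muscle"))
    for k in range(6):
        nuclei.append(Nucleus(160.0 + 12.0 * k, 40.0, 2.0, "brain"))

    def gene(name, regions_, pattern, n, **params):
        return GeneSpec(name, tuple(regions_), pattern, n * spots_scale, params)

    genes = (
        gene("mus-nucin", ["muscle"], "nucleus_enriched", 3000, sigma=1.5),
        gene("mus-nucout", ["muscle"], "nucleus_depleted", 3000, well_radius=6.0, well_depth=0.05),
        gene("mus-stripeA", ["muscle"], "striped", 3000, period=12.0, phase=0.0, axis="x"),
        gene("mus-stripeB", ["muscle"], "striped", 3000, period=12.0, phase=np.pi, axis="x"),
        gene("mus-terminal", ["muscle"], "terminal_enriched", 1500, decay_scale=8.0, axis="x", end="low"),
        gene("brain-m1", ["brain"], "uniform", 2500),
        gene("brain-m2", ["brain"], "uniform", 2000),
        gene("gut-apical", ["gut"], "boundary_apical", 2000, decay_scale=4.0),
        gene("gut-basal", ["gut"], "boundary_basal", 2000, decay_scale=4.0),
        gene("gut-m1", ["gut"], "uniform", 1500),
        gene("fat-m1", ["fat"], "uniform", 2000),
        gene("epi-m1", ["epithelia"], "uniform", 2500),
        gene("heart-m1", ["heart"], "uniform", 800),
    )
    spec = SceneSpec(
        width=300.0,
        height=170.0,
        regions=regions,
        nuclei=tuple(nuclei),
        genes=genes,
    )
    return simulate_scene(spec, seed)


def exclusive_markers(scene: SyntheticScene) -> dict[str, list[str]]:
    """Region -> genes whose declared region set is exactly that region."""
    out: dict[str, list[str]] = {r.name: [] for r in scene.spec.regions}
    for g in scene.spec.genes:
        if len(g.regions) == 1:
            out[g.regions[0]].append(g.name)
    return out
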