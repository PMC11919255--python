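"""Domain types and file I/O shared by every analysis stage.

Conventions
-----------
* World coordinates are in micrometres (µm); x grows rightward and y grows
  downward, matching raster-image indexing.
* Pixel ``(i, j)`` of a raster covers the half-open square
  ``[origin_x + j*s, origin_x + (j+1)*s) x [origin_y + i*s, origin_y + (i+1)*s)``
  where ``s`` is the pixel size in µm; its *center* therefore sits at
  ``origin + (index + 0.5) * s``.
* Gene identifiers are compared case-sensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GenePanel",
    "SpotTable",
    "RasterMask",
    "AnalysisConfig",
    "SpotTableFormatError",
    "MaskFormatError",
    "read_spot_table",
    "write_spot_table",
    "read_mask",
    "write_mask",
    "write_count_matrix",
    "read_count_matrix",
]


class SpotTableFormatError(ValueError):
    """Raised when a spot-table file does not match the declared layout."""


class MaskFormatError(ValueError):
    """Raised when a mask image cannot be interpreted as single-channel binary."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePanel:
    """Ordered, unique list of gene identifiers with optional per-gene metadata."""

    genes: tuple[str, ...]
    metadata: Mapping[str, Mapping[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if len(genes) != len(set(genes)):
            raise ValueError("gene identifiers must be unique")
        if any(not g for g in genes):
            raise ValueError("gene identifiers must be non-empty")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in set(self.genes)

    def index(self, gene: str) -> int:
        return self.genes.index(gene)


@dataclass
class SpotTable:
    """Per-molecule records: gene identity plus 2D position in µm.

    ``data`` holds columns ``gene``, ``x``, ``y``, ``sample`` (and optionally
    ``z``, which is preserved on round trip but ignored by all 2D analyses).
    ``n_dropped`` records off-panel rows discarded by the reader.
    """

    data: pd.DataFrame
    panel: GenePanel
    n_dropped: int = 0

    REQUIRED = ("gene", "x", "y", "sample")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SpotTableFormatError(f"spot table missing columns: {missing}")
        coords = df[["x", "y"]].to_numpy(dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("spot coordinates must be finite")
        off_panel = set(df["gene"]) - set(self.panel.genes)
        if off_panel:
            raise ValueError(f"genes outside the declared panel: {sorted(off_panel)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes_present(self) -> list[str]:
        present = set(self.data["gene"])
        return [g for g in self.panel.genes if g in present]

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    def subset(self, genes: Iterable[str] | None = None, sample: str | None = None) -> "SpotTable":
        df = self.data
        if genes is not None:
            df = df[df["gene"].isin(set(genes))]
        if sample is not None:
            df = df[df["sample"] == sample]
        return SpotTable(df.reset_index(drop=True), self.panel)

    def coords(self, gene: str | None = None) -> np.ndarray:
        """(n, 2) array of x, y in µm, optionally restricted to one gene."""
        df = self.data if gene is None else self.data[self.data["gene"] == gene]
        return df[["x", "y"]].to_numpy(dtype=float)


@dataclass
class RasterMask:
    """Binary raster anchored in world (µm) coordinates.

    ``origin_x``/``origin_y`` give the µm position of the *corner* of pixel
    (0, 0); the pixel center is half a pixel further along each axis.
    """

    pixels: np.ndarray
    pixel_size: float = 0.138
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise MaskFormatError("mask raster must be 2D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())

    def world_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map µm coordinates to (row, col) indices (floor; may be out of range)."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.origin_y) / self.pixel_size).astype(int)
        return row, col

    def pixel_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """World µm coordinates of pixel centers."""
        x = self.origin_x + (np.asarray(col, dtype=float) + 0.5) * self.pixel_size
        y = self.origin_y + (np.asarray(row, dtype=float) + 0.5) * self.pixel_size
        return x, y

    def foreground_centers(self) -> np.ndarray:
        """(n, 2) array of x, y µm centers of all foreground pixels."""
        rows, cols = np.nonzero(self.pixels)
        x, y = self.pixel_center(rows, cols)
        return np.column_stack([x, y])

    def contains(self, x, y) -> np.ndarray:
        """True where the world point falls on a foreground pixel."""
        row, col = self.world_to_pixel(x, y)
        inside = (row >= 0) & (row < self.shape[0]) & (col >= 0) & (col < self.shape[1])
        out = np.zeros_like(inside, dtype=bool)
        out[inside] = self.pixels[row[inside], col[inside]]
        return out


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable constants of the pipeline, with the published defaults."""

    disk_diameter: float = 4.0        # µm; colocalization disk diameter
    pixel_size: float = 0.138         # µm per raster pixel
    bin_pixels: int = 36              # grid bin width in pixels
    min_square_counts: int = 3        # strict > filter on square totals
    size_factor: float = 10_000.0     # normalization target sum
    z_threshold: float = 1.0          # gene-set assignment cutoff
    lasso_penalty: float = 1.0        # positive-lasso alpha
    weight_threshold: float = 0.2     # confident-match cutoff on lasso weights
    min_gene_spots: int = 100         # distance-profile gene filter
    coloc_resolution: float = 0.1     # µm raster cell for disk-union areas
    # tissue-mask morphology recipe, in application order
    blur_kernel: int = 5
    blur_sigma: float = 1.0
    erosion_kernels: tuple[int, ...] = (5, 4)
    dilation_kernel: int = 50
    dilation_repeats: int = 3
    final_blur_kernel: int = 5
    final_blur_sigma: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("disk_diameter", "pixel_size", "size_factor", "coloc_resolution"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("bin_pixels", "min_gene_spots", "dilation_kernel", "dilation_repeats"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_square_counts < 0:
            raise ValueError("min_square_counts must be >= 0")
        for name in ("z_threshold", "lasso_penalty", "weight_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def grid_side(self) -> float:
        """Side length of one pseudo-bulk square in µm."""
        return self.bin_pixels * self.pixel_size

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "erosion_kernels" in raw:
            raw["erosion_kernels"] = tuple(raw["erosion_kernels"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# spot tables
# ---------------------------------------------------------------------------


def read_spot_table(
    path: str | Path,
    panel: GenePanel,
    *,
    sep: str = "\t",
    gene_col: str = "gene",
    x_col: str = "x",
    y_col: str = "y",
    z_col: str = "z",
    sample_col: str = "sample",
    default_sample: str = "sample0",
    px_to_um: float | None = None,
) -> SpotTable:
    """Read a delimited spot table; rows with off-panel genes are dropped.

    Coordinates are taken as µm unless ``px_to_um`` is given, in which case
    x/y(/z) are multiplied by that scale.
    """
    df = pd.read_csv(path, sep=sep)
    required = {gene_col, x_col, y_col}
    missing = required - set(df.columns)
    if missing:
        raise SpotTableFormatError(f"{path}: missing required columns {sorted(missing)}")

    rename = {gene_col: "gene", x_col: "x", y_col: "y"}
    if z_col in df.columns:
        rename[z_col] = "z"
    if sample_col in df.columns:
        rename[sample_col] = "sample"
    df = df.rename(columns=rename)
    if "sample" not in df.columns:
        df["sample"] = default_sample

    for col in ("x", "y") + (("z",) if "z" in df.columns else ()):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            raise SpotTableFormatError(
                f"{path}: non-numeric {col!r} at row index {int(np.flatnonzero(bad)[0])}"
            )
        df[col] = values.astype(float)
        if px_to_um is not None:
            df[col] = df[col] * px_to_um

    on_panel = df["gene"].isin(set(panel.genes))
    n_dropped = int((~on_panel).sum())
    if n_dropped:
        logger.info("read_spot_table: dropped %d rows with off-panel genes", n_dropped)
    df = df[on_panel].reset_index(drop=True)

    cols = ["gene", "x", "y", "sample"] + (["z"] if "z" in df.columns else [])
    return SpotTable(df[cols], panel, n_dropped=n_dropped)


def write_spot_table(table: SpotTable, path: str | Path, *, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def read_mask(
    path: str | Path,
    pixel_size: float | None = None,
    origin: tuple[float, float] | None = None,
) -> RasterMask:
    """Load a single-channel raster image as a binary mask (nonzero = foreground).

    Scale and origin come from the arguments, or from a ``<file>.yaml`` sidecar
    written by :func:`write_mask`, falling back to the 0.138 µm/px default.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        arr = imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise MaskFormatError(
            f"{path}: expected single-channel image, got shape {arr.shape}"
        )
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    if pixel_size is None:
        pixel_size = float(meta.get("pixel_size", 0.138))
    if origin is None:
        origin = (float(meta.get("origin_x", 0.0)), float(meta.get("origin_y", 0.0)))
    return RasterMask(arr != 0, pixel_size=pixel_size, origin_x=origin[0], origin_y=origin[1])


def write_mask(mask: RasterMask, path: str | Path) -> None:
    """Write mask as 8-bit TIFF/PNG plus a YAML sidecar with scale and origin."""
    path = Path(path)
    img = (mask.pixels.astype(np.uint8)) * 255
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img)
    else:
        from imageio.v3 import imwrite

        imwrite(path, img)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(
            {
                "pixel_size": float(mask.pixel_size),
                "origin_x": float(mask.origin_x),
                "origin_y": float(mask.origin_y),
            },
            fh,
        )


# ---------------------------------------------------------------------------
# count matrices (lossless round trip; see grid_quant.CountGrid)
# ---------------------------------------------------------------------------


def write_count_matrix(grid, out_dir: str | Path, fmt: str = "mtx") -> None:
    """Write a CountGrid as Matrix Market triplets + label TSVs, or a dense TSV.

    ``fmt='mtx'`` produces ``matrix.mtx`` (squares x genes), ``genes.tsv`` and
    ``squares.tsv`` (square metadata incl. centroids); ``fmt='dense'`` produces
    a single ``matrix.tsv`` with the square metadata as leading columns.
    """
    from scipy import io as spio
    from scipy import sparse

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    squares = grid.squares.copy()
    if fmt == "mtx":
        mat = sparse.csr_matrix(grid.counts)
        spio.mmwrite(
            out_dir / "matrix.mtx", mat, field="integer" if not grid.normalized else "real"
        )
        pd.Series(list(grid.genes), name="gene").to_csv(
            out_dir / "genes.tsv", sep="\t", index=False
        )
        squares.to_csv(out_dir / "squares.tsv", sep="\t", index=False)
    elif fmt == "dense":
        dense = pd.DataFrame(grid.counts, columns=list(grid.genes))
        pd.concat([squares.reset_index(drop=True), dense], axis=1).to_csv(
            out_dir / "matrix.tsv", sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    with open(out_dir / "grid.yaml", "w") as fh:
        yaml.safe_dump(
            {"side": float(grid.side), "normalized": bool(grid.normalized), "format": fmt},
            fh,
        )


def read_count_matrix(out_dir: str | Path):
    """Inverse of :func:`write_count_matrix` (both formats)."""
    from scipy import io as spio

    from .grid_quant import CountGrid

    out_dir = Path(out_dir)
    with open(out_dir / "grid.yaml") as fh:
        meta = yaml.safe_load(fh)
    if meta["format"] == "mtx":
        counts = np.asarray(spio.mmread(out_dir / "matrix.mtx").todense())
        genes = tuple(pd.read_csv(out_dir / "genes.tsv", sep="\t")["gene"].astype(str))
        squares = pd.read_csv(out_dir / "squares.tsv", sep="\t")
    else:
        df = pd.read_csv(out_dir / "matrix.tsv", sep="\t")
        meta_cols = ["sample", "row", "col", "cx", "cy"]
        genes = tuple(c for c in df.columns if c not in meta_cols)
        squares = df[meta_cols]
        counts = df[list(genes)].to_numpy()
    if not meta["normalized"]:
        counts = counts.astype(np.int64)
    squares = squares.assign(sample=squares["sample"].astype(str))
    return CountGrid(
        counts=counts,
        squares=squares,
        genes=genes,
        side=float(meta["side"]),
        normalized=bool(meta["normalized"]),
    )
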