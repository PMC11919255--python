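"""Pseudo-bulk quantification on a square grid.

Spots are binned per sample into half-open squares of side
``bin_pixels * pixel_size`` µm (36 px * 0.138 µm/px = 4.968 µm by default),
counts are summed per square and gene, low-count squares are dropped with a
strict ``total > min_square_counts`` rule, and retained squares are
size-factor normalized and log transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AnalysisConfig, SpotTable

__all__ = ["CountGrid", "rasterize", "filter_squares", "normalize_grid"]

SQUARE_COLUMNS = ["sample", "row", "col", "cx", "cy"]


class NormalizationStateError(RuntimeError):
    """Raised when normalizing a grid that is already normalized."""


@dataclass
class CountGrid:
    """Squares x genes matrix with per-square location metadata.

    ``squares`` has one row per retained square: sample id, (row, col) bin
    indices, and the square-center world coordinates ``cx``/``cy`` in µm
    (``(index + 0.5) * side`` plus the per-sample offset).
    """

    counts: np.ndarray
    squares: pd.DataFrame
    genes: tuple[str, ...]
    side: float
    normalized: bool = False
    sample_offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.genes = tuple(self.genes)
        if self.counts.shape != (len(self.squares), len(self.genes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.squares)} squares x {len(self.genes)} genes"
            )
        if not self.normalized and self.counts.size and (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_squares(self) -> int:
        return len(self.squares)

    @property
    def square_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [
                self.squares.reset_index(drop=True),
                pd.DataFrame(self.counts, columns=list(self.genes)),
            ],
            axis=1,
        )


def rasterize(spots: SpotTable, config: AnalysisConfig | None = None) -> CountGrid:
    """Bin spots into the pseudo-bulk grid; total counts are conserved.

    Each spot lands in exactly one square per axis via
    ``floor(coordinate / side)`` (half-open bins, floor toward -inf, so
    negative coordinates are valid). Binning is done per sample with the bin
    origin fixed at world (0, 0) for every sample.
    """
    config = config or AnalysisConfig()
    side = config.grid_side
    df = spots.data
    genes = spots.panel.genes
    gene_index = {g: i for i, g in enumerate(genes)}

    if len(df) == 0:
        squares = pd.DataFrame(columns=SQUARE_COLUMNS)
        return CountGrid(np.zeros((0, len(genes)), dtype=np.int64), squares, genes, side)

    col = np.floor(df["x"].to_numpy() / side).astype(np.int64)
    row = np.floor(df["y"].to_numpy() / side).astype(np.int64)
    keys = pd.DataFrame(
        {"sample": df["sample"].to_numpy(), "row": row, "col": col,
         "gene_i": df["gene"].map(gene_index).to_numpy()}
    )
    grouped = keys.groupby(["sample", "row", "col", "gene_i"], sort=True).size()

    square_keys = grouped.index.droplevel("gene_i").unique()
    square_pos = {k: i for i, k in enumerate(square_keys)}
    counts = np.zeros((len(square_keys), len(genes)), dtype=np.int64)
    for (sample, r, c, gi), n in grouped.items():
        counts[square_pos[(sample, r, c)], gi] = n

    squares = pd.DataFrame(list(square_keys), columns=["sample", "row", "col"])
    squares["cx"] = (squares["col"] + 0.5) * side
    squares["cy"] = (squares["row"] + 0.5) * side
    return CountGrid(counts, squares, genes, side)


def filter_squares(grid: CountGrid, min_square_counts: int | None = None) -> CountGrid:
    """Keep squares whose total count is strictly greater than the threshold."""
    if grid.normalized:
        raise NormalizationStateError("filter before normalizing")
    threshold = 3 if min_square_counts is None else min_square_counts
    keep = grid.square_totals > threshold
    return CountGrid(
        grid.counts[keep],
        grid.squares.loc[keep].reset_index(drop=True),
        grid.genes,
        grid.side,
        normalized=False,
        sample_offsets=dict(grid.sample_offsets),
    )


def normalize_grid(grid: CountGrid, size_factor: float = 10_000.0) -> CountGrid:
    """Per-square size-factor normalization followed by log1p.

    value = log(1 + size_factor * count / square_total), natural log. The
    result is flagged; normalizing twice raises.
    """
    if grid.normalized:
        raise NormalizationStateError("grid is already normalized")
    if not size_factor > 0:
        raise ValueError("size_factor must be > 0")
    totals = grid.square_totals.astype(float)
    if (totals == 0).any():
        raise ValueError("cannot normalize squares with zero total; filter first")
    values = np.log1p(size_factor * grid.counts / totals[:, None])
    return CountGrid(
        values,
        grid.squares.copy(),
        grid.genes,
        grid.side,
        normalized=True,
        sample_offsets=dict(grid.sample_offsets),
    )
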