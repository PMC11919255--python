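"""Gene-set signature scoring and square labelling.

Each category's raw score is the summed expression of its genes per square;
scores are z-normalized per category across all squares (pooled over
samples, population standard deviation). A square is assigned to a category
when its z exceeds the threshold (default 1); conflicts are resolved either
by a fixed category hierarchy (default) or by the maximal z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core_io import GenePanel
from .grid_quant import CountGrid

logger = logging.getLogger(__name__)

__all__ = ["GeneSetConfig", "SquareLabels", "score_gene_sets", "assign_labels"]

UNASSIGNED = "unassigned"


class GeneSetConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSetConfig:
    """Category -> gene list plus a priority hierarchy (highest first).

    Genes may be shared between categories and count in each.
    """

    gene_sets: dict[str, tuple[str, ...]]
    hierarchy: tuple[str, ...]
    z_threshold: float = 1.0

    def __post_init__(self) -> None:
        cats = set(self.gene_sets)
        if set(self.hierarchy) != cats or len(self.hierarchy) != len(cats):
            raise GeneSetConfigError(
                "hierarchy must contain every category exactly once"
            )

    def restricted_to_panel(self, panel: GenePanel) -> "GeneSetConfig":
        """Drop (and log) listed genes absent from the panel."""
        in_panel = set(panel.genes)
        sets = {}
        for cat, genes in self.gene_sets.items():
            kept = tuple(g for g in genes if g in in_panel)
            dropped = [g for g in genes if g not in in_panel]
            if dropped:
                logger.warning("gene set %r: dropped off-panel genes %s", cat, dropped)
            if not kept:
                raise GeneSetConfigError(f"category {cat!r} has no genes in the panel")
            sets[cat] = kept
        return GeneSetConfig(sets, self.hierarchy, self.z_threshold)

    @classmethod
    def from_yaml(cls, path) -> "GeneSetConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            gene_sets={k: tuple(v) for k, v in raw["gene_sets"].items()},
            hierarchy=tuple(raw["hierarchy"]),
            z_threshold=float(raw.get("z_threshold", 1.0)),
        )


@dataclass
class SquareLabels:
    """Per-square scores, z-scores and (once assigned) category labels."""

    squares: pd.DataFrame                # copy of the grid's square metadata
    categories: tuple[str, ...]
    raw_scores: np.ndarray               # (squares, categories)
    z_scores: np.ndarray                 # (squares, categories); NaN if variance 0
    labels: np.ndarray | None = None     # object array, category or "unassigned"
    mode: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.squares.reset_index(drop=True).copy()
        for k, cat in enumerate(self.categories):
            df[f"z_{cat}"] = self.z_scores[:, k]
        if self.labels is not None:
            df["label"] = self.labels
        return df


def score_gene_sets(grid: CountGrid, genesets: GeneSetConfig) -> SquareLabels:
    """Raw category scores (summed gene expression) and pooled z-scores.

    z uses the population (n-denominator) standard deviation across all
    squares of all samples; a category with zero variance gets z = NaN and
    can never be assigned.
    """
    gene_index = {g: i for i, g in enumerate(grid.genes)}
    for cat, genes in genesets.gene_sets.items():
        missing = [g for g in genes if g not in gene_index]
        if missing:
            raise GeneSetConfigError(
                f"category {cat!r} lists genes absent from the grid: {missing}"
            )
    cats = tuple(genesets.hierarchy)
    raw = np.column_stack(
        [
            grid.counts[:, [gene_index[g] for g in genesets.gene_sets[cat]]].sum(axis=1)
            for cat in cats
        ]
    ).astype(float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (raw - mean) / sd, np.nan)
    return SquareLabels(grid.squares.copy(), cats, raw, z)


def assign_labels(
    scores: SquareLabels, genesets: GeneSetConfig, mode: str = "hierarchy"
) -> SquareLabels:
    """Attach a label per square.

    hierarchy: highest-priority category with z > threshold, else unassigned.
    argmax: category of maximal z among those above threshold; exact ties
    broken by hierarchy priority.
    """
    if mode not in ("hierarchy", "argmax"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    thr = genesets.z_threshold
    z = scores.z_scores
    cats = scores.categories
    n = z.shape[0]
    labels = np.full(n, UNASSIGNED, dtype=object)
    with np.errstate(invalid="ignore"):
        above = z > thr  # NaN compares False: variance guard
    if mode == "hierarchy":
        for k, cat in enumerate(cats):  # cats already in priority order
            sel = above[:, k] & (labels == UNASSIGNED)
            labels[sel] = cat
    else:
        any_above = above.any(axis=1)
        masked = np.where(above, z, -np.inf)
        # first maximal index in priority order breaks exact ties
        best = masked.argmax(axis=1)
        labels[any_above] = np.asarray(cats, dtype=object)[best[any_above]]
    return SquareLabels(scores.squares, cats, scores.raw_scores, z, labels, mode)
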