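# spatialfly

Analysis toolkit for single-molecule spatial transcriptomics spot tables
(multiplexed smFISH / Molecular Cartography style data). Given a table of
detected mRNA molecules — one record per molecule with gene identity and 2D
position in µm — the package provides:

- **Disk-overlap colocalization** (`coloc_cluster`): every molecule becomes a
  4 µm disk, disks of one species are merged into a union surface, and the
  asymmetric proximity of species A in B is `overlap / surface_B`. The
  symmetric species distance `2 − (prox_AinB + prox_BinA)` (0 = perfect
  overlap, 2 = none) feeds Ward hierarchical clustering of genes.
- **Grid pseudo-bulk quantification** (`grid_quant`): rasterization into
  4.968 µm squares (36 px × 0.138 µm/px), a strict `total > 3` square filter,
  and size-factor-10,000 log normalization.
- **Gene-set signature labelling** (`signature_scoring`): per-category summed
  expression, pooled z-scoring, and `z > 1` assignment with hierarchy or
  max-score conflict resolution.
- **Subcellular localization statistics** (`localization_stats`): tissue-mask
  construction from marker spots (Gaussian blur 5×5 σ1 → erosions 5×5, 4×4 →
  dilation 50×50 ×3 → blur), per-spot nearest-nucleus Euclidean distances with
  median/density-peak summaries, and marker specificity (fraction of a gene's
  spots inside a region mask).
- **Positive-lasso label transfer** (`label_transfer`): per-square nonnegative
  lasso (`alpha = 1`) against single-cell cluster mean profiles, assignment by
  highest weight among weights `> 0.2`; plus gene–gene correlation concordance
  between two modalities.
- **Synthetic scenes** (`synthetic_data`): seeded generator of multi-region
  layouts with nuclei and per-gene spatial patterns (uniform,
  nucleus-enriched/-depleted, complementary stripes, terminal enrichment,
  apical/basal boundary decay) at 0.14 µm localization precision, so the whole
  pipeline is testable without external data.

## CLI

A single entry point with seeded, reproducible subcommands:

```sh
spatialfly simulate  --seed 0 --out run/sim            # synthetic scene (or --scene scene.yaml)
spatialfly rasterize --spots run/sim/spots.tsv --out run/grid --normalize
spatialfly score     --grid run/grid --genesets genesets.yaml --out run/labels.tsv
spatialfly coloc     --spots run/sim/spots.tsv --k 3 --out run/coloc
spatialfly nucdist   --spots run/sim/spots.tsv --nuclei run/sim/nuclei.tiff --out run/nucdist
spatialfly specificity --spots run/sim/spots.tsv --region run/sim/region_muscle.tiff --out run/spec.tsv
spatialfly transfer  --grid run/grid --profiles profiles.tsv --out run/transfer.tsv
spatialfly run       --seed 0 --out run/all            # simulate → rasterize → score + manifest
```

Spot tables are TSV (`gene`, `x`, `y[, z, sample]`, µm); masks are
single-channel TIFF/PNG with a YAML sidecar carrying `pixel_size` and origin;
count matrices are Matrix Market (`matrix.mtx` + `genes.tsv` + `squares.tsv`)
or dense TSV. Analysis constants live in one YAML mirroring
`AnalysisConfig`.

## Conventions

World coordinates are µm, x rightward, y downward (image convention); pixel
`(i, j)` covers a half-open square, grid bins are half-open with floor toward
−∞, and gene identifiers are case-sensitive. All randomness flows from a
single seed per scene/run.
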