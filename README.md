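# spiscreen

Quantitative analysis of arrayed yeast colony screens in which forced
binary protein associations are assayed for growth defects against two
independent controls. The package covers the full pipeline:

- **colony_quant** — grid fitting and colony-area measurement from scanned
  plate images (1536-colony grids, per-cell Otsu thresholding).
- **screen_stats** — per-plate normalization (plate median or on-plate
  controls), log growth ratios (LGR) against each control, robust
  median/MAD z-scores, and spatial smoothing that subtracts a local
  background to remove plate-position gradients.
- **spi_calling** — sequential retest confirmation: rank by smoothed z,
  confirm in batches of 20 with 16 replicates (effect-size floor + exact
  one-sided rank-sum against both controls), track batchwise FDR with a
  3-point moving average and stop at 40%; plus haploid/diploid suppression
  classification.
- **profile_analysis** — screen-screen Spearman correlation, hierarchical
  centroid-linkage clustering (1 − Pearson distance), interaction frequency
  and abundance binning, Fisher/hypergeometric enrichment with BH
  correction, interaction-density ranking against a known-interaction
  network (permutation null), and headline summary proportions.
- **fluor_quant** — 3D fluorescence focus quantification: intensity
  thresholding, fixed physical dilations (~600 nm core margin, 2.4 µm
  background ring), background-subtracted integrated intensity, and
  whole-cell totals from maximum projections.
- **synthetic_data** — generators for screens, retest plates, plate
  images, annotation tables, interaction networks and fluorescence stacks
  with planted ground truth, so every stage is testable closed-loop.
- **io_cli** — TSV colony/score tables, plate layouts, Cluster 3.0
  `.cdt`/`.gtr`/`.atr` exports, YAML configuration, and the CLI.

## CLI

All stages are available as subcommands of `spiscreen`:

```sh
spiscreen simulate --n-queries 2000 --n-spis 30 --seed 1 --out scratch/sim
spiscreen score --fusion scratch/sim/colonies_fusion.tsv \
    --control-target-only scratch/sim/colonies_control_target_only.tsv \
    --control-gbp-only scratch/sim/colonies_control_gbp_only.tsv \
    --out scratch/scores.tsv
spiscreen retest scratch/scores.tsv scratch/sim/truth.tsv --out scratch/retest
spiscreen cluster matrix.tsv --prefix scratch/clustered
spiscreen focus stack.tif --voxel-size 300 100 100 --threshold 99.5 \
    --threshold-mode percentile --out scratch/foci.tsv
```

A full run (simulate → score → smooth → retest → cluster → report) is
driven by a single YAML config and is byte-reproducible from config + seed:

```sh
spiscreen run config.yaml
```

with e.g.

```yaml
seed: 7
output_dir: scratch/report
simulate: {n_queries: 2000, n_spis: 30}
smoothing: {window: 3, statistic: median}
retest: {max_candidates: 80, stop_fdr: 0.40}
```

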