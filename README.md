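# soilconet

Downstream analysis of heavy-metal-contaminated agricultural soil
microbiomes: pollution indices, diversity statistics, environment–taxon
association, and bacterial–fungal co-occurrence networks with Zi–Pi
keystone-taxon classification — exercised end-to-end on synthetic
communities with known ground truth.

The pipeline starts from ASV count tables (16S bacteria + ITS fungi),
sample metadata (group label, seven metal concentrations, ten
physicochemical variables) and a metal background-value table. A
first-class synthetic-data module generates all of these with planted
statistical structure (correlated taxon modules spanning both domains, hub
and connector taxa, metal-responding taxa, correlated metal gradients) so
every stage can be validated against ground truth.

## Components

| module | what it does |
|---|---|
| `soilconet.synthetic` | Gaussian-copula community generator with `SyntheticTruth` ground truth |
| `soilconet.tabular_io` | strict TSV readers/writers for counts, taxonomy, metadata, backgrounds; GraphML / edge-list export |
| `soilconet.pollution` | contamination factor (CF = measured/background), pollution load index (geometric mean of CFs), pollution classes |
| `soilconet.community` | Good's coverage, bias-corrected Chao1, Gini–Simpson; Bray–Curtis, PCoA (plus covariance-PCA mode), ANOSIM, Mann–Whitney |
| `soilconet.association` | Spearman (vectorised, exact mode for small n), Benjamini–Hochberg, env–taxon heatmaps, Mantel tests, genus-level cross-domain correlation |
| `soilconet.network` | co-occurrence graph (\|rho\| > r AND BH q < alpha), topology summary, greedy modularity modules, Zi/Pi, keystone roles (module hub Zi > 2.5, connector Pi > 0.62, network hub both) |
| `soilconet.experiments` | recovery/calibration benchmarks used by the acceptance suite |
| `soilconet.pipeline` / `soilconet.cli` | end-to-end orchestration with a checksum manifest |

## CLI

```bash
soilconet simulate --out data/ --seed 1            # synthetic bundle + truth
soilconet pollution --metadata data/metadata.tsv \
    --background data/background_values.tsv --out pollution.tsv
soilconet diversity --table data/bacteria_counts.tsv --out div.tsv
soilconet ordination --table data/bacteria_counts.tsv --groups data/metadata.tsv
soilconet assoc --bact data/bacteria_counts.tsv --fungi data/fungi_counts.tsv \
    --taxonomy data/taxonomy.tsv --meta data/metadata.tsv --rank phylum --out assoc.tsv
soilconet network --bact data/bacteria_counts.tsv --fungi data/fungi_counts.tsv \
    --taxonomy data/taxonomy.tsv --r 0.7 --alpha 0.05 \
    --out net.graphml --summary topo.tsv
soilconet run-all --config run.yaml --out out/ --seed 1
```

`run-all` accepts a YAML config with either a `simulate:` section
(SyntheticConfig overrides) or paths to existing tables, plus thresholds
(`r_threshold`, `alpha`, `min_prevalence`, `genus_threshold`) and
permutation counts. Every run writes a `manifest.json` with the seed,
thresholds, headline results, and SHA-256 checksums of all outputs; the
same config + seed reproduces the manifest bit-for-bit.

## File formats

All tables are tab-separated UTF-8 with `.` decimals.

- **counts**: taxa as rows (first header cell `taxon_id`), samples as
  columns; samples-as-rows (`sample`) is auto-detected on read.
- **taxonomy**: `taxon_id`, `domain`, then `phylum … genus`
  (`unclassified` for unknown ranks).
- **metadata**: optional `# metal_units: mg_per_kg|ng_per_g` header line
  (converted to mg/kg exactly once on read), then `sample`, `group`, metal
  and physicochemical columns.
- **networks**: GraphML (nodes carry domain/module/Zi/Pi/role, edges carry
  rho/q/sign) or `source  target  rho  q  sign` edge lists.

## Notes and caveats

- Association analyses use raw Spearman on relative abundances without
  compositional correction, replicating the emulated workflow; this is a
  known limitation, not an endorsement.
- The network prevalence filter (taxon present in ≥ 1/3 of samples by
  default) is configurable; the emulated workflow's exact pre-filtering is
  unstated.
- Boundary values of classification thresholds (CF exactly 1/3/6, PLI
  exactly 1, Zi exactly 2.5, Pi exactly 0.62) fall in the lower class /
  peripheral role, following the strict inequalities of the definitions.
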