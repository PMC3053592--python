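# chromex

Toolkit for testing whether chromatin spatial proximity (Hi-C contact) is
associated with gene co-expression after controlling for shared
transcription-factor regulation. It implements:

- **core_io** — domain types and readers/writers: BED6 gene annotations,
  chrom.sizes, dense/COO contact-matrix TSVs, TF→target edge lists,
  mutual-rank tables, an OBO ontology subset (`is_a` / `part_of`), gene→term
  annotations, and the pair-table / results outputs.
- **hic_metrics** — distance-expected profile, observed/expected
  normalization, the bin-level Pearson correlation matrix (PC),
  overlap-proportional gene→bin weights, weighted gene-pair interaction
  values, and percentile ranks.
- **pair_metrics** — per-pair statistics: transcription-control similarity
  (TCS = 1 − |symmetric difference of TF sets| / sum of TF-set sizes),
  normalized distance (midpoint separation / chromosome length), mutual-rank
  lookup, and the central gene-pair table.
- **go_semsim** — Wang-method semantic similarity: S-values over ancestor
  closures with relation-specific edge weights (is_a 0.8, part_of 0.6), term
  similarity, and best-match-average gene similarity.
- **analysis_pipeline** — pair-table assembly, cross-cell-type rank matching
  (percentile-rank difference < 5%), stratification (distant pairs, TCS
  zero/nonzero, co-expressed MR ≤ 50), 20-group equal-size binned correlation
  tests with Bonferroni correction (0.05 / 4 panels = 0.0125), and the
  co-expressed-vs-rest Welch t-test.
- **synthetic_data** — a seed-deterministic generator producing complete
  input bundles: Poisson contact maps with power-law distance decay and
  compartment-block boosts, a factor-model expression matrix whose
  within-block correlation (β) couples co-expression to contact structure,
  mutual ranks, a bipartite TF network, and a small ontology with optional
  proximity-coupled annotations (γ).

## CLI

```sh
# generate a synthetic bundle (null or strong-coupling preset)
chromex simulate --preset strong --seed 1 --out bundle/

# run the full analysis; writes results.json, pair_table.tsv, per-panel
# group-mean TSVs and a stage-count log
chromex run --config bundle/config.yaml --out results/

# build only the gene-pair table
chromex pairs --config bundle/config.yaml --out pairs.tsv

# pairwise gene-level ontology similarity
chromex gosim --obo bundle/ontology.obo --annotations bundle/gene_go.tsv --out gosim.tsv
```

`chromex simulate` accepts `--config sim.yaml` overriding any
`SimulationConfig` field (chromosome count/length, resolution, gene/TF
counts, decay exponent, block count, κ, β, γ, seed, …).

## Pair-table format

Headered TSV preceded by one `#meta` JSON line. Fixed column order:
`gene_a, gene_b, chrom, norm_dist, mutual_rank, tcs, go_sim`, then per cell
type `oh_<ct>, pc_<ct>, rank_pct_<ct>`. Missing values are written `NA`.
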