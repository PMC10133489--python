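# medipreset

Analysis pipeline for MeDIP-chip promoter tiling arrays, built around a
nutritional-epigenetics study design: offspring of protein-restricted rat
dams (stroke-prone spontaneously hypertensive rats) receive different
postnatal diets, and renal promoter methylation is compared across diet
groups to find differentially methylated regions (DMRs) and genes whose
methylation state is *reset* by the postnatal diet.

The package implements, as tested reusable components:

- **Normalization** of two-channel (IP/input) probe intensities:
  log2 ratio → per-sample median centering → cross-sample quantile
  normalization → positional linear smoothing.
- **Peak/DMR calling** with a sliding-window (1,500 bp) one-sided
  Kolmogorov–Smirnov test. Each probe gets a p-score
  `−log10 p` with `p = exp(−2 D⁺² mn/(m+n))`, where
  `D⁺ = sup_x [F̂_rest(x) − F̂_window(x)]` compares the probes in the
  window around it against the rest of the array. Runs of ≥ 2 probes with
  p-score ≥ 2 become peaks; peaks within 500 bp are merged. Group
  comparisons run on the per-probe difference of group means and on its
  negation, yielding hyper- and hypomethylated DMRs, each summarized by a
  PeakDM value (mean differential log2 ratio over member probes).
- **Promoter CpG classes** from sequence: HCP (some 500-bp window in
  −0.7 kb…+0.2 kb of the TSS with GC ≥ 0.55 and CpG observed/expected
  ≥ 0.6), LCP (no window with O/E ≥ 0.4), ICP (everything else), with
  CpG O/E = (#CpG × length)/(#C × #G).
- **Reset-gene classification**: a gene with a baseline DMR
  (mLP-CN vs mCN-CN) is reset by a postnatal diet comparison when that
  comparison shows a PeakDM of opposite sign, giving six categories
  ({hyper, hypo} × {both, LP only, HP only}), plus a completeness check
  that the resetting diet actually returned methylation to control level.
- **Gene-set enrichment** of DMR gene lists: one-tailed hypergeometric
  test on GMT gene sets, Enrichment Score = −log10(p).
- **Synthetic studies** with planted promoter classes, DMRs and reset
  genes, emitting a truth table every downstream result can be scored
  against.

## Worked example

Simulate a six-group study (n = 5 per group, 500 promoters tiled by nine
~210-bp-spaced probes each), run the full pipeline, and inspect the
reset-gene summary:

```bash
cat > study.yaml << 'YAML'
outdir: demo_out
simulate:
  n_promoters: 500
  seed: 1
YAML
medip-reset run --config study.yaml
cat demo_out/reset_summary.tsv
```

which prints (seed 1):

```
        both    LP_only HP_only total
hyper   1       11      5       17
hypo    4       4       6       14
total   5       15      11      31
```

Each cell counts genes whose baseline DMR direction (rows) was reversed
by the postnatal low-protein diet, the high-protein diet, or both
(columns). The per-gene table `demo_out/reset_genes.tsv` carries the
PeakDM values behind every call and a `complete` flag marking genes whose
methylation fully returned to the control level, and
`demo_out/dmr_counts.tsv` tabulates hyper-/hypomethylated DMR counts per
comparison and promoter CpG class. Against this run's planted truth
(44 baseline DMR genes), the baseline comparison recovers all 44, with
8 extra noise calls.

Every stage is also exposed as its own subcommand (`simulate`,
`preprocess`, `classify-promoters`, `call-dmrs`, `classify-reset`,
`enrich`) and as plain library functions.

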