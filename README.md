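# coexmeta

Integrated gene-level and network-level meta-analysis of paired (pre/post
intervention) transcriptomic studies, built around the contrast between
skeletal-muscle **disuse** (immobilization / bed rest) and **resistance
exercise training (RET)**.  Multiple independent microarray-style studies
measure the same genes on paired biopsies; no single study is powered to
separate signal from platform noise, so evidence is combined at two levels:

- **Gene level.**  Within each study, differential expression post vs. pre
  is estimated with empirical-Bayes moderated paired *t*-tests (per-gene
  variances shrunk toward a prior (d₀, s₀²) fitted by matching moments of
  log s²_g to a scaled-F model).  Right-tailed per-study *p*-values are
  combined across a condition's studies with Stouffer's method,
  Z = Σᵢ Φ⁻¹(1 − pᵢ)/√k, corrected by Benjamini–Hochberg, and a gene is
  declared DE only if q ≤ 0.1, |meta mean log₂FC| > 0.1, **and** its
  fold-change has one direction in every study.
- **Network level.**  Per study, a signed weighted adjacency
  Adj = (½(1 + cor))^β (β = lowest integer reaching scale-free fit R² ≥ 0.8)
  becomes a topological overlap matrix (TOM); studies are calibrated by
  single-quantile scaling and combined by the parallel (element-wise)
  minimum into a consensus TOM.  Average-linkage clustering of 1 − cTOM
  yields consensus modules (≥ 50 genes, merged while eigengenes correlate
  > 0.75 in every study), whose eigengenes (first principal components) are
  tested for pre/post regulation with the same Stouffer/BH machinery.
- **Across conditions.**  Rank–rank hypergeometric overlap (RRHO) on genes
  ranked by sign(log₂FC)·(−log₁₀ q) splits regulation into concordant,
  discordant, and condition-unique classes; module labels are matched
  between networks by Fisher-overlap; consensus hub genes (module
  membership Stouffer-Z above the within-module 85th percentile) are
  overlaid with the RRHO classes to nominate candidate regulators.

Because the original multi-study compendia require external downloads, the
package ships a first-class synthetic-data generator that emulates the
study design — several independent paired studies per condition, planted
co-expression modules with dataset-consistent structure, planted gene- and
module-level effects — so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (2000 genes, two groups × three studies × 20 pairs) and write their
tables under `results/`:

```bash
cd analysis
python 01_simulate_study.py
python 02_gene_level_meta.py
python 03_consensus_networks.py
python 04_cross_condition.py
python 05_hubs_and_enrichment.py
```

Output from a run (seed 17, the default):

```
group A: 446 DE genes (231 up / 215 down); sensitivity on planted background effects: 0.99
group A: beta per dataset {'A1': 6, 'A2': 5, 'A3': 5}; 5 consensus modules
  (sizes [80, 80, 78, 77, 76]), ARI vs planted modules 0.98
  M1: up-regulated (mean eigengene shift +0.75 SD, q = 3.41e-42)
  M5: down-regulated (mean eigengene shift -0.84 SD, q = 2.38e-42)
RRHO up-up: optimum at ranks (220, 200), -log10 p = 83.1, 125 genes
planted shared: 94% labelled common-concordant-*
planted unique_A: 98% labelled unique-A-*
M1: 12 vs 11 hubs, 3 shared (p = 2.65e-05)
group A: 60 hubs, 35 hub+RRHO candidates
ORA of group-A up-regulated genes: enriched terms ['PLANTED_M1']
```

Reading this: both planted module shifts are recovered as differentially
regulated modules with the planted signs; the RRHO up-up quadrant peaks
far above chance because 100 shared-direction genes plus the commonly
up-shifted module M1 overlap between conditions; hub selection takes the
top 15% of each module by consensus membership; and the only enriched
gene-set term is the planted up-shifted module.  Discordant (inverted)
genes are the hardest class — their quadrant signal is weak at this
problem size — which the script reports honestly.

The same pipeline is scriptable through a CLI
(`coexmeta simulate | preprocess | gene-meta | network | module-meta |
compare | hubs | enrich | run-all`, with `--config`, `--seed`,
`--outdir`); `coexmeta run-all` performs the whole two-group study in one
call and writes a JSON run report carrying the configuration and seed.

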