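# reprokit

Analysis toolkit for the first 72 hours of OSKM-mediated fibroblast
reprogramming, re-built as a tested, reusable Python pipeline.

Somatic fibroblasts can be reprogrammed to induced pluripotent stem (iPS)
cells by over-expressing OCT4 (POU5F1), SOX2, KLF4 and c-MYC (OSKM).
`reprokit` implements the computational side of studying the *initiation*
of that process from a duplicate-design bead-array time course — donor
fibroblasts, samples at 24/48/72 h post-transduction, and iPS/ES
references — together with a seeded synthetic-data module that plants
known ground truth so that every stage can be verified quantitatively at
desk scale. It is aimed at computational biologists analysing
reprogramming (or other perturbation) time courses on detection-call
platforms.

## What it computes

- **Detection calls and filtering** — per-probe presence when the
  detection p-value `p < 0.01` (strict), and an analysis set of probes
  present in both duplicates of at least one sample group.
- **Differential expression vs donor** — log2 + quantile normalization,
  empirical-Bayes moderated t (per-probe variances shrunk toward a
  method-of-moments prior; `prior_df=0` gives the ordinary pooled t),
  Benjamini–Hochberg adjustment, and the regulated flag
  `p_adj < 0.05 AND |log2FC| > log2(1.5)`. Each probe gets a 5-character
  regulation profile over (24 h, 48 h, 72 h, iPS, ES), e.g. `01111`.
- **Gene-set dynamics** — pluripotency-associated probes (present in all
  pluripotent samples, absent in both donor replicates), their mirror-image
  fibroblast-associated set, activation fractions across the time course,
  annotation-term subsetting (e.g. cell-surface markers), and a classic
  one-sided hypergeometric enrichment test.
- **Fuzzy c-means clustering** (fuzzifier `m = 1.7`) of z-scored regulation
  profiles with 0.5 alpha-core membership filtering.
- **EMT-suppression signature** — rank every gene by mean Pearson
  correlation with a packaged 36-gene positive-EMT seed set
  (SNAI1/2, TWIST1, VIM, CDH2, …); validate the ranking by a leave-out
  recovery test with a cumulative-binomial null
  (`p = P(X ≥ x₁), X ~ Binomial(n_draws, 1/n_bins)`); quantify EMT
  suppression per cell state by the Spearman rank correlation between the
  most down-regulated genes and their EMT ranks, plus a binomial
  over-representation test — positive, growing ρ means EMT genes are
  progressively silenced, as expected when the mesenchymal-to-epithelial
  transition is under way.
- **Interaction-network analysis** — a mixed graph of undirected
  protein–protein and directed regulatory edges; the subnetwork merging all
  shortest paths from the OSKM sources to pluripotency-regulated sinks; and
  a weighted betweenness variant per intermediate node:
  `score(v) = (#source→sink shortest paths through v) / (mean length of those paths)`,
  favouring nodes on many *short* shortest paths, with high/low
  classification at a score quantile and extraction of paths through a
  named intermediate (e.g. POU5F1→FRAT2→GSK3B→MYCN).

## Worked example

```python
from importlib import resources
from reprokit import synthetic, expression, emt
from reprokit.io import read_sif, read_roles
from reprokit.network import InteractionNetwork, score_nodes, paths_through

# a coordinated synthetic study: compendium + time course sharing one
# planted EMT module with progressively growing suppression
sc = synthetic.simulate_emt_timecourse(rng_seed=0)
calls = expression.call_detection(sc.matrix)
states = ["t24", "t48", "t72", "iPS", "ES"]
de = {c: expression.differential_expression(sc.matrix, calls, c) for c in states}

ranked = emt.seed_rank(sc.compendium, sc.seeds)
rec = emt.recovery_test(sc.compendium, sc.seeds, rng_seed=0)
print(rec.bin_counts.tolist(), f"p = {rec.p_value:.3g}")
print(emt.signature_table(ranked, de, states).round(3))
```

prints

```
[80, 0, 0, 0, 0, 0, 0, 0, 0, 0] p = 1e-80
         rho  p_spearman  p_binomial  n_down
state
t24   -0.049       0.600       0.715     115
t48    0.179       0.024       0.000     159
t72    0.474       0.000       0.000     175
iPS    0.658       0.000       0.000     164
ES     0.714       0.000       0.000     173
```

All 80 left-out seed genes land in the first rank decile (a perfectly
recoverable seed, p = 10⁻⁸⁰), and the suppression statistic reproduces the
planted dynamics: no association at 24 h, then a monotonically rising ρ
with significant Spearman and binomial p-values from 48 h onward.

The packaged curated network illustrates the node scoring:

```python
data = resources.files("reprokit.data")
net = InteractionNetwork.from_edges(read_sif(data / "fig4_network.sif"),
                                    read_roles(data / "fig4_roles.tsv"))
print(score_nodes(net))
print(paths_through(net, via="GSK3B"))
```

```
        path_count  mean_path_length     score
node
FRAT2            1               3.0  0.333333
GSK3B            1               3.0  0.333333
CREBBP           1               3.0  0.333333
GLI3             1               3.0  0.333333
[('POU5F1', 'FRAT2', 'GSK3B', 'MYCN')]
```

Each intermediate sits on one source→sink shortest path of length 3, so
its score is 1/3; the extraction through GSK3B returns the regulatory
path from POU5F1 to MYCN.

## Command line

```bash
reprokit simulate --n-probes 2000 --seed 1 --outdir study/   # synthetic study TSVs
reprokit run --seed 1 --outdir run/                          # full pipeline bundle
reprokit rank --compendium compendium.tsv                    # EMT seed ranking
reprokit network --network net.sif --roles roles.tsv --via GSK3B
reprokit report --rundir run/
```

`reprokit run` executes every stage from one YAML config (thresholds
default to detection 0.01, p_adj 0.05, fold change 1.5, m 1.7, alpha 0.5)
and writes one TSV per stage plus `manifest.json`; identical config and
seed give byte-identical outputs.

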