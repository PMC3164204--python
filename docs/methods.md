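# Methods

This note documents the models and procedures `reprokit` implements, the
parameters that matter, what the synthetic generators emulate (and do
not), and the numerical and design choices taken where more than one
reasonable option existed.

## Study design being modelled

A bead-array expression time course of OSKM-transduced human foreskin
fibroblasts: duplicate donor samples, duplicate samples at 24, 48 and
72 h post-transduction, and duplicate iPS-like and ES-like pluripotent
references. Each probe/sample pair carries a signal intensity and a
detection p-value (the significance of signal over bead background).
Probe identifiers are opaque strings and one row is one probe
throughout; no probe→gene collapsing is attempted.

## Normalization and detection calls

Raw intensities are log2-transformed and quantile-normalized across
samples (ties receive the mean reference quantile; a single column is
returned unchanged, making the transform idempotent). A
variance-stabilizing background-correction step was deliberately not
modelled: the synthetic surrogate is generated directly on the log2
scale, and on real data the quantile step removes the same between-array
location/scale differences the analysis depends on.

Presence is `detection_p < 0.01`, strictly — a p-value of exactly 0.01
is absent. The analysis set keeps probes present in *both* replicates of
at least one sample group; a group with a single replicate degenerates
to presence in that sample, with a logged warning.

## Differential expression

For contrast group vs donor, `log2FC` is the difference of group means.
Per-probe pooled variances s² (df = n₁+n₂−2) are shrunk toward a prior
via the standard empirical-Bayes posterior
s²ₚₒₛₜ = (d₀s₀² + df·s²)/(d₀ + df); the moderated t uses df + d₀ degrees
of freedom. The prior (d₀, s₀²) is estimated by method of moments on
log s² under the scaled-F model (solving trigamma(d₀/2) = var(log s²) −
trigamma(df/2)); when the observed spread of log s² is at or below the
χ² floor, d₀ → ∞ and all probes share s₀² (normal-tail p-values).
`prior_df = 0` disables shrinkage and reproduces the ordinary pooled
two-sample t exactly — this identity is asserted in the tests against an
independently hand-coded formula. Benjamini–Hochberg adjustment is
applied across the analysis set (the alternative — adjusting across all
probes — is a config choice; the analysis set is the default since those
are the probes the analysis actually interrogates).

A probe is *regulated* when `p_adj < 0.05` and `|log2FC| > log2(1.5)`
(symmetric up/down); the per-probe regulation profile is the 5-character
0/1 string over (24 h, 48 h, 72 h, iPS, ES).

## Gene-set dynamics

Pluripotency-associated probes are present (group-level: in all
replicates) in every pluripotent line and absent in both donor
replicates; fibroblast-associated is the mirror image. The strict
"all pluripotent samples" reading is the default; `require_all=False`
relaxes to group-level presence in at least one pluripotent group. The
two sets are disjoint by construction and this is asserted on every
input. Activation fractions are group-level presence fractions per time
point, with denominators the set sizes.

Term enrichment is the classic one-sided hypergeometric test with BH
adjustment — no ontology-graph decorrelation (elim/weight-style
algorithms) is attempted, since the analysis only needs a ranking of
candidate terms and the classic test is exactly verifiable against
combinatorial enumeration (asserted for universes ≤ 25, including the
closed-form 1/C(20,5) = 1/15504 case).

## Fuzzy c-means clustering

Profiles (per-probe log2FC vectors over the five contrasts, by default)
are z-scored per row before clustering, so only profile *shape* is
clustered — a deliberate choice matching soft-clustering practice for
expression time courses; consequently planted mean-level differences are
invisible to it, and test fixtures plant shape differences. Standard FCM
alternation with Euclidean distance: memberships
u ∝ (1/d²)^(1/(m−1)) normalized per row, centroids Σuᵐx/Σuᵐ, fuzzifier
m = 1.7 by default, tol 1e-6, max 300 sweeps, initial centroids c
distinct profiles drawn by the seeded RNG. Distances are normalized by
the row minimum before exponentiation so small fuzzifiers (m → 1, large
exponents) cannot overflow; a profile coinciding with a centroid takes
membership 1 there (the limit convention). The objective Σuᵐd² is
recorded per iteration and is non-increasing. Cluster count defaults to
9 in the pipeline config but is a free parameter — no automatic
selection rule is provided. The 0.5 alpha-core keeps a profile only if
its maximal membership reaches the threshold.

## EMT-suppression signature

The seed set is a packaged list of 36 positive-EMT genes (GMT fixture).
Similarity is the mean Pearson correlation of a gene's profile with each
seed profile, computed after z-scoring every sample — which makes the
ranking invariant to affine rescaling of any single array — with
self-correlation excluded for seed genes, zero-variance genes scored 0,
and ties broken lexicographically for determinism. Mean Spearman
correlation is available as an alternative similarity.

The recovery test removes ⌈10%⌉ of the seeds per repeat, re-ranks with
the reduced seed, and records each left-out gene's rank bin (equal-width
deciles of the universe; positions are recorded per gene, not per
left-out group). The p-value is the exact upper binomial tail
P(X ≥ x₁), X ~ Binomial(n_draws, 1/n_bins) for the first-bin count.

The suppression statistic takes, per cell state, all significantly
down-regulated genes (regulated, negative log2FC; a `top_n` cutoff is
optional), ordered most-down-first by ascending moderated t, pairs each
with its position in the EMT ranking, and reports the Spearman ρ with
the large-sample t-approximation p-value. Positive ρ means the most
down-regulated genes are the most EMT-like. The companion
over-representation test counts the overlap x of the top-k EMT genes
with the top-m down-regulated genes and reports P(X ≥ x),
X ~ Binomial(m, k/N) — the binomial (rather than hypergeometric) tail is
the primary statistic by design, with the hypergeometric as the natural
alternative when m/N is not small. Because the binomial p-value is a
discrete statistic, its null distribution is checked by tail calibration
(false-positive rate at 0.05, central mean) rather than a
Kolmogorov–Smirnov test against the continuous uniform, which is the
appropriate uniformity check only for the continuous Spearman p-value.

## Interaction-network scoring

The graph mixes undirected protein–protein edges with directed
regulatory edges; traversal follows regulatory edges regulator→target
only (an `undirected_all` flag collapses everything to undirected, since
directionality conventions differ between interaction databases). Edge
lengths are unit hops; no confidence weighting. For every
(source, sink) pair all shortest paths are enumerated; the subnetwork is
their union; unreachable pairs contribute nothing. Each node outside the
source/sink sets accumulates, across pairs, the count of shortest paths
containing it as an interior node and their pooled mean length; its
score is count/mean-length (0 when it lies on no path), so many short
paths beat few long ones. Sources and sinks themselves are not scored —
the centrality targets intermediates. High/low classification thresholds
at the 0.75 quantile of the positive scores, boundary ties classified
high; both choices are configurable. All three operations are verified
exactly against exhaustive DFS enumeration on hundreds of seeded random
mixed graphs (≤ 12 nodes), plus a conservation identity on interior
path counts.

## Synthetic data: what it emulates, and what it does not

`simulate_expression` plants: (i) differential probes (half up, half
down) whose offset from the donor mean is effect·growth^i at time point
i, with pluripotent groups carrying the final time point's effect;
(ii) detection-state probes — pluripotency-like probes absent in donor,
switched on for a growing fraction of the set across time points
(defaults 0.1/0.3/0.6) and present in all pluripotent samples, with
fibroblast-like probes mirroring them; (iii) optional EMT probes with
per-state down-regulation magnitudes scaled by per-probe weights.
Detection p-values are drawn directly from the planted state —
Uniform(0, 0.009] when expressed, Uniform(0.02, 1) when not — rather
than from a bead-level noise model: only the 0.01 threshold semantics
matter downstream. Noise is Gaussian on the log2 scale (default sd 0.25
per observation, a free parameter chosen as a plausible inter-duplicate
variability; it is not an empirical estimate). iPS and ES are treated as
replicate groups of one pluripotent state; an optional line-offset sd
models distinct lines. There is no batch effect, no probe-sequence
bias, and no intensity-dependent variance — so passing tests demonstrate
the *procedures* are correct and well calibrated under a clean noise
model, not that real arrays meet these assumptions.

`simulate_compendium` plants one co-expressed module via a shared latent
factor (per-gene loadings optional); genes outside the module are
independent. `simulate_network` plants source→sink paths and adds
background edges that are rejected if they would shorten a planted
pair's distance.

`simulate_emt_timecourse` couples the two: module genes receive
descending latent loadings (0.95→0.35) and planted suppression weights
(1.6→0.4) in the same order, so the co-expression ranking and the
planted down-regulation ordering share one latent ordering. Per-state
suppression multipliers default to (0.2, 1.05, 1.7, 2.3, 3.6) over
(24 h, 48 h, 72 h, iPS, ES) against a constant-magnitude background of
planted DE (log2FC 1.0, 12% of probes): at 24 h the module sits below
the significance threshold (ρ ≈ 0), then progressively overtakes the
background, driving a monotonically increasing ρ. These multipliers,
the module size (36 seeds + 24 extra members) and the compendium size
(200 samples) were fixed once by a design-time power analysis at the
generator's default noise so that the planted ordering is recoverable
with comfortable margin by duplicate samples; they are study-design
constants of the scenario, not tuning knobs.

## Problem sizes and runtime

All simulation-based checks run at desk scale: 2 000-probe matrices with
duplicate groups, 200-sample compendia, ≤ 12-node graphs for oracle
equivalence (200 graphs), 50 seeded runs for the suppression-recovery
check, 200 runs for DE calibration/power, 500 runs for null-uniformity.
The full test suite completes in well under a minute on one CPU; the
acceptance script in a few seconds.

## Known limitations

- The moderated-t prior is a method-of-moments fit, not a full
  maximum-likelihood F-fit; with very few probes the prior estimate is
  noisy (shrinkage then defaults toward the pooled average).
- The seed-ranking similarity is a stand-in for unpublished seed-sorting
  internals; conclusions about a *specific* external compendium require
  that compendium.
- Quantile normalization assumes comparable global distributions across
  samples; strong global shifts (e.g. transcriptional amplification)
  violate this.
- The GEO series-matrix loader handles the standard text export with
  detection columns; it is a convenience, not a general GEO client.
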