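"""EMT-suppression signature machinery.

MET (the reverse of the epithelial-to-mesenchymal transition) is a
prerequisite of fibroblast reprogramming, so genes that drive EMT should
be progressively silenced on the way to pluripotency.  The signature
works from a small seed set of positive EMT genes: every gene in a
co-expression compendium is ranked by its mean correlation with the
seeds (seed-based ranking); a leave-out recovery test with a cumulative
binomial null calibrates the ranking; the suppression statistic rank-
correlates (Spearman) the most down-regulated genes of each cell state
with their positions in the EMT ranking, and a binomial test checks
over-representation of top EMT genes among the top down-regulated ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: packaged seed set of 36 positive EMT genes
EMT_SEED_GMT = "emt_seed_genes.gmt"


def load_emt_seeds() -> list[str]:
    """The packaged 36-gene positive-EMT seed list."""
    from .io import read_gmt

    with resources.as_file(resources.files("reprokit") / "data" / EMT_SEED_GMT) as p:
        sets = read_gmt(p)
    return sets["EMT_POSITIVE"]


def _standardized(rows: pd.DataFrame) -> np.ndarray:
    arr = rows.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    zero = sd[:, 0] == 0
    sd[sd == 0] = 1.0
    z = (arr - mean) / sd
    z[zero] = 0.0
    return z


def seed_rank(compendium: pd.DataFrame, seeds) -> pd.DataFrame:
    """Rank every gene by mean Pearson correlation with the seed profiles.

    Samples (columns) are z-scored before computing gene-gene
    correlations, so the ranking ignores per-array location/scale.
    Seed genes exclude their self-correlation.  Zero-variance genes get
    similarity 0 (with a warning); seeds missing from the compendium are
    dropped with a warning.  Ties break lexicographically by gene id.

    Returns a DataFrame indexed by gene in rank order with columns
    ``rank`` (1 = most seed-like) and ``similarity``.
    """
    if compendium.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    seeds = list(dict.fromkeys(seeds))
    present = [s for s in seeds if s in compendium.index]
    missing = sorted(set(seeds) - set(present))
    if missing:
        logger.warning("dropping %d seed gene(s) absent from compendium: %s",
                       len(missing), missing[:5])
    if not present:
        raise ValueError("empty effective seed set")
    n = compendium.shape[1]
    zero_var = (compendium.std(axis=1, ddof=1) == 0).to_numpy()
    # per-sample standardization first: similarity is then invariant to
    # affine rescaling of any single array in the compendium
    cols = compendium.to_numpy(dtype=float)
    cmean = cols.mean(axis=0, keepdims=True)
    csd = cols.std(axis=0, ddof=0, keepdims=True)
    csd[csd == 0] = 1.0
    compendium = pd.DataFrame((cols - cmean) / csd, index=compendium.index,
                              columns=compendium.columns)
    Z = _standardized(compendium)
    if zero_var.any():
        logger.warning("%d zero-variance gene(s); similarity set to 0",
                       int(zero_var.sum()))
    seed_pos = compendium.index.get_indexer(present)
    corr = Z @ Z[seed_pos].T / (n - 1)          # genes x seeds
    sims = corr.mean(axis=1)
    k = len(present)
    if k > 1:
        # remove each seed's self-correlation (exactly 1) from its mean
        sims[seed_pos] = (corr[seed_pos].sum(axis=1) - 1.0) / (k - 1)
    else:
        sims[seed_pos] = 0.0
    sims[zero_var] = 0.0
    order = sorted(range(len(sims)), key=lambda i: (-sims[i], compendium.index[i]))
    out = pd.DataFrame({"similarity": sims[order]},
                       index=compendium.index[order])
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


@dataclass
class RecoveryTestResult:
    """Leave-out recovery histogram and its cumulative-binomial p-value."""

    bin_counts: np.ndarray
    n_draws: int
    p_value: float
    n_bins: int

    def __post_init__(self) -> None:
        if int(self.bin_counts.sum()) != self.n_draws:
            raise ValueError("bin counts must sum to the number of draws")


def binomial_tail(n: int, x: int, p: float) -> float:
    """Exact upper tail P(X >= x), X ~ Binomial(n, p)."""
    if x <= 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, p))


def recovery_test(compendium: pd.DataFrame, seeds, leave_out_fraction: float = 0.1,
                  n_repeats: int = 20, n_bins: int = 10,
                  rng_seed: int = 0) -> RecoveryTestResult:
    """Leave-out validation of the seed ranking.

    Per repeat, a random ``leave_out_fraction`` of the seeds is removed,
    the compendium is re-ranked with the reduced seed, and each left-out
    gene's rank falls into one of ``n_bins`` equal-width bins of the
    universe.  A well-performing seed piles left-out genes into the first
    bin; the p-value is the upper binomial tail P(X >= x1) with
    X ~ Binomial(n_draws, 1/n_bins) and x1 the first-bin count.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if n_repeats < 1:
        raise ValueError("need at least 1 repeat")
    seeds = [s for s in dict.fromkeys(seeds) if s in compendium.index]
    n_out = math.ceil(leave_out_fraction * len(seeds))
    if n_out < 1 or n_out >= len(seeds):
        raise ValueError("leave-out fraction leaves no usable split")
    rng = np.random.default_rng(rng_seed)
    N = compendium.shape[0]
    counts = np.zeros(n_bins, dtype=int)
    for _ in range(n_repeats):
        out_idx = rng.choice(len(seeds), size=n_out, replace=False)
        left_out = [seeds[i] for i in out_idx]
        reduced = [s for s in seeds if s not in left_out]
        ranked = seed_rank(compendium, reduced)
        pos = ranked.loc[left_out, "rank"].to_numpy()
        bins = np.minimum(((pos - 1) * n_bins) // N, n_bins - 1).astype(int)
        np.add.at(counts, bins, 1)
    n_draws = int(counts.sum())
    p = binomial_tail(n_draws, int(counts[0]), 1.0 / n_bins)
    return RecoveryTestResult(counts, n_draws, p, n_bins)


@dataclass
class SignatureTestResult:
    """Per-cell-state suppression statistics (Table-1-shaped row)."""

    state: str
    rho: float | None
    p_spearman: float | None
    p_binomial: float | None
    n_genes: int


def _down_ordered(de: pd.DataFrame, significant_only: bool = True) -> pd.Index:
    """Gene ids ordered most-down-regulated first (ascending moderated t)."""
    sub = de[de["direction"] == "down"] if significant_only else de[de["log2fc"] < 0]
    return sub.sort_values(["t", "log2fc"]).index


def suppression_rank_correlation(ranked: pd.DataFrame, de: pd.DataFrame,
                                 state: str, top_n: int | None = None) -> SignatureTestResult:
    """Spearman rank correlation between down-regulation and EMT ranks.

    The ``top_n`` most significantly down-regulated genes (default: all
    significantly down ones), ordered most-down-first, are paired with
    their positions in the EMT-ranked list; positive rho means EMT-like
    genes are preferentially down-regulated.  P-value from the standard
    large-sample t approximation.
    """
    down = _down_ordered(de)
    if top_n is not None:
        if top_n > len(down):
            raise ValueError(f"top_n={top_n} exceeds the {len(down)} "
                             "significantly down-regulated genes")
        down = down[:top_n]
    in_ranked = down.isin(ranked.index)
    if (~in_ranked).any():
        logger.warning("%d down-regulated gene(s) absent from the ranked list; dropped",
                       int((~in_ranked).sum()))
        down = down[in_ranked]
    if len(down) < 3:
        raise ValueError("fewer than 3 paired genes")
    down_rank = np.arange(1, len(down) + 1)
    emt_pos = ranked.loc[down, "rank"].to_numpy()
    rho, p = stats.spearmanr(down_rank, emt_pos)
    return SignatureTestResult(state, float(rho), float(p), None, len(down))


def overrepresentation_binomial(ranked: pd.DataFrame, de: pd.DataFrame, state: str,
                                top_k_emt: int, top_m_down: int) -> SignatureTestResult:
    """Binomial over-representation of top EMT genes among top down genes.

    x = |top-k EMT genes ∩ top-m most down-regulated genes|;
    p = P(X >= x) with X ~ Binomial(m, k/N), N the universe size.
    """
    N = len(ranked)
    if not (0 < top_k_emt <= N and 0 < top_m_down <= N):
        raise ValueError("top_k_emt and top_m_down must lie in 1..N")
    down = _down_ordered(de, significant_only=False)
    down = down[down.isin(ranked.index)]
    if not len(down):
        raise ValueError("empty down-regulated list")
    top_down = set(down[:top_m_down])
    top_emt = set(ranked.index[:top_k_emt])
    x = len(top_down & top_emt)
    p = binomial_tail(len(top_down), x, top_k_emt / N)
    return SignatureTestResult(state, None, None, p, x)


def signature_table(ranked: pd.DataFrame, de_results: dict[str, pd.DataFrame],
                    states, top_n: int | None = None,
                    top_k_emt: int = 200, top_m_down: int = 200) -> pd.DataFrame:
    """One suppression-test row per cell state (rho, p_spearman, p_binomial)."""
    rows = []
    for state in states:
        de = de_results[state]
        try:
            sup = suppression_rank_correlation(ranked, de, state, top_n)
            rho, p_s, n = sup.rho, sup.p_spearman, sup.n_genes
        except ValueError as exc:
            logger.warning("state %s: %s", state, exc)
            rho, p_s, n = float("nan"), float("nan"), 0
        over = overrepresentation_binomial(ranked, de, state, top_k_emt, top_m_down)
        rows.append((state, rho, p_s, over.p_binomial, n))
    return pd.DataFrame(rows, columns=["state", "rho", "p_spearman",
                                       "p_binomial", "n_down"]).set_index("state")
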