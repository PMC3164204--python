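import numpy as np
import pandas as pd
import pytest

from reprokit.emt import (binomial_tail, load_emt_seeds,
                          overrepresentation_binomial, recovery_test,
                          seed_rank, signature_table,
                          suppression_rank_correlation)
from reprokit.expression import call_detection, differential_expression
from reprokit.synthetic import simulate_compendium, simulate_emt_timecourse

from ._oracles import binomial_tail_sum

STATES = ["t24", "t48", "t72", "iPS", "ES"]


def _fake_de(genes, t_values, regulated_down):
    return pd.DataFrame({
        "log2fc": -np.abs(t_values) / 4.0,
        "t": t_values,
        "p_raw": 0.001, "p_adj": 0.001,
        "regulated": [g in regulated_down for g in genes],
        "direction": ["down" if g in regulated_down else "none" for g in genes],
    }, index=genes)


class TestSeedRank:
    def test_packaged_seed_list(self):
        seeds = load_emt_seeds()
        assert len(seeds) == 36
        assert {"SNAI1", "TWIST1", "VIM", "CDH2"} <= set(seeds)

    def test_module_occupies_top_ranks(self):
        genes = [f"G{i:04d}" for i in range(546)]
        module = genes[:46]
        table = simulate_compendium(546, 100, module, 0.9, rng_seed=1,
                                    gene_ids=genes)
        ranked = seed_rank(table, module[:36])
        assert set(ranked.index[:46]) == set(module)

    def test_copy_of_seed_ranks_above_background(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 30))
        X[1] = X[0]  # exact copy of the seed profile
        table = pd.DataFrame(X, index=[f"g{i}" for i in range(20)])
        ranked = seed_rank(table, ["g0"])
        assert ranked.loc["g1", "rank"] == 1  # seed itself scores 0 (self excluded)

    def test_output_is_permutation_with_monotone_scores(self):
        table = simulate_compendium(50, 20, [f"G{i:05d}" for i in range(8)],
                                    0.7, rng_seed=3)
        ranked = seed_rank(table, [f"G{i:05d}" for i in range(8)])
        assert sorted(ranked.index) == sorted(table.index)
        assert np.all(np.diff(ranked["similarity"].to_numpy()) <= 1e-12)

    def test_invariant_to_sample_order_and_affine_rescaling(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(30, 12)),
                             index=[f"g{i}" for i in range(30)])
        seeds = ["g0", "g1", "g2"]
        base = seed_rank(table, seeds)
        shuffled = table.iloc[:, rng.permutation(12)]
        assert list(seed_rank(shuffled, seeds).index) == list(base.index)
        scaled = table.copy()
        scaled.iloc[:, 3] = 10.0 + 2.5 * scaled.iloc[:, 3]
        assert list(seed_rank(scaled, seeds).index) == list(base.index)

    def test_missing_seeds_and_empty_seed_set(self):
        table = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 6)),
                             index=list("abcde"))
        ranked = seed_rank(table, ["a", "zz"])
        assert len(ranked) == 5
        with pytest.raises(ValueError, match="empty"):
            seed_rank(table, ["zz"])


class TestRecoveryTest:
    def test_perfect_seed_hits_first_bin_closed_form(self):
        """A tightly co-expressed module puts every left-out seed in the
        first decile: 20 draws all first-bin gives p = 0.1**20 = 1e-20."""
        genes = [f"G{i:04d}" for i in range(2000)]
        seeds = genes[:36]
        table = simulate_compendium(2000, 80, seeds, 0.95, rng_seed=5,
                                    gene_ids=genes)
        res = recovery_test(table, seeds, leave_out_fraction=0.1,
                            n_repeats=5, n_bins=10, rng_seed=6)
        assert res.n_draws == 20
        assert res.bin_counts[0] == 20
        assert res.p_value == pytest.approx(1e-20, rel=1e-9)

    def test_p_matches_exact_tail_summation(self):
        for n, x in [(20, 20), (20, 5), (30, 3), (10, 0)]:
            assert binomial_tail(n, x, 0.1) == pytest.approx(
                binomial_tail_sum(n, x, 0.1), rel=1e-9)

    def test_bin_counts_conserve_draws(self):
        genes = [f"G{i:04d}" for i in range(300)]
        table = simulate_compendium(300, 30, genes[:20], 0.5, rng_seed=7,
                                    gene_ids=genes)
        res = recovery_test(table, genes[:20], n_repeats=8, rng_seed=8)
        assert res.bin_counts.sum() == res.n_draws == 8 * 2

    def test_parameter_validation(self):
        genes = [f"G{i:04d}" for i in range(50)]
        table = simulate_compendium(50, 10, genes[:10], 0.5, rng_seed=0,
                                    gene_ids=genes)
        with pytest.raises(ValueError):
            recovery_test(table, genes[:10], n_bins=1)
        with pytest.raises(ValueError):
            recovery_test(table, genes[:10], n_repeats=0)


class TestSuppressionRankCorrelation:
    def test_identical_ordering_gives_rho_one(self):
        genes = [f"g{i}" for i in range(10)]
        ranked = pd.DataFrame({"rank": range(1, 11), "similarity": 0.0},
                              index=genes)
        de = _fake_de(genes, np.arange(-10.0, 0.0), set(genes))
        res = suppression_rank_correlation(ranked, de, "t24")
        assert res.rho == pytest.approx(1.0)

    def test_reversed_ordering_gives_rho_minus_one(self):
        genes = [f"g{i}" for i in range(10)]
        ranked = pd.DataFrame({"rank": range(1, 11), "similarity": 0.0},
                              index=genes)
        de = _fake_de(genes, -np.arange(1.0, 11.0), set(genes))
        res = suppression_rank_correlation(ranked, de, "t24")
        assert res.rho == pytest.approx(-1.0)

    def test_requires_three_paired_genes(self):
        genes = ["g0", "g1", "g2"]
        ranked = pd.DataFrame({"rank": [1, 2, 3]}, index=genes)
        de = _fake_de(genes, np.array([-3.0, -2.0, -1.0]), {"g0", "g1"})
        with pytest.raises(ValueError, match="3 paired"):
            suppression_rank_correlation(ranked, de, "t24")

    def test_progressive_suppression_recovered_single_run(self):
        sc = simulate_emt_timecourse(rng_seed=0)
        ranked = seed_rank(sc.compendium, sc.seeds)
        calls = call_detection(sc.matrix)
        de = {c: differential_expression(sc.matrix, calls, c) for c in STATES}
        tab = signature_table(ranked, de, STATES)
        rhos = tab["rho"].to_numpy()
        assert np.all(np.diff(rhos) > 0)
        assert np.all(tab["p_spearman"].to_numpy()[1:] < 0.05)


class TestOverrepresentationBinomial:
    def test_matches_bruteforce_summation(self):
        assert binomial_tail(50, 20, 0.1) == pytest.approx(
            binomial_tail_sum(50, 20, 0.1), rel=1e-9)

    def test_overlap_counting_on_contrived_lists(self):
        genes = [f"g{i}" for i in range(100)]
        ranked = pd.DataFrame({"rank": range(1, 101)}, index=genes)
        # the 10 most down-regulated genes are exactly EMT ranks 1-5 and 50-54
        down = genes[:5] + genes[49:54] + genes[80:]
        t_vals = np.zeros(100)
        for pos, g in enumerate(down):
            t_vals[genes.index(g)] = -100.0 + pos
        de = _fake_de(genes, t_vals, set(down))
        res = overrepresentation_binomial(ranked, de, "t24",
                                          top_k_emt=10, top_m_down=10)
        assert res.n_genes == 5  # overlap x
        assert res.p_binomial == pytest.approx(
            binomial_tail_sum(10, 5, 10 / 100), rel=1e-9)

    def test_zero_overlap_certain(self):
        genes = [f"g{i}" for i in range(20)]
        ranked = pd.DataFrame({"rank": range(1, 21)}, index=genes)
        t_vals = np.zeros(20)
        t_vals[10:] = np.arange(-10.0, 0.0)
        de = _fake_de(genes, t_vals, set(genes[10:]))
        res = overrepresentation_binomial(ranked, de, "t24",
                                          top_k_emt=5, top_m_down=5)
        assert res.p_binomial == pytest.approx(1.0)

    def test_tail_monotone_in_overlap(self):
        ps = [binomial_tail(50, x, 0.2) for x in range(0, 51)]
        assert np.all(np.diff(ps) < 0)
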