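import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from reprokit.expression import (ExpressionMatrix, adjust_bh, call_detection,
                                 differential_expression, normalize,
                                 pca_projection, quantile_normalize,
                                 regulation_profile)

from ._oracles import bh_bruteforce, pooled_t


def _matrix(intens, det, groups):
    samples = list(intens.columns)
    return ExpressionMatrix(intens, det, pd.Series(groups, index=samples))


class TestQuantileNormalize:
    def test_two_column_hand_computed(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 6.0, 8.0]})
        out = quantile_normalize(df)
        expected = [2.5, 4.0, 5.5]
        assert np.allclose(out["a"], expected)
        assert np.allclose(out["b"], expected)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(8, 2, size=(50, 4)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once, twice)

    def test_single_column_unchanged_and_log2_only(self):
        raw = pd.DataFrame({"s1": [1.0, 4.0, 16.0]})
        m = normalize(raw, pd.Series({"s1": "donor"}))
        assert np.allclose(m.intensities["s1"], [0.0, 2.0, 4.0])

    def test_nonpositive_intensity_names_probe_and_sample(self):
        raw = pd.DataFrame({"s1": [1.0, -2.0]}, index=["pA", "pB"])
        with pytest.raises(ValueError, match=r"pB.*s1"):
            normalize(raw, pd.Series({"s1": "donor"}))


class TestDetectionCalls:
    @pytest.mark.parametrize("p, expect", [(0.009, True), (0.010, False)])
    def test_strict_threshold(self, p, expect):
        intens = pd.DataFrame({"donor-a": [8.0], "donor-b": [8.0]}, index=["p0"])
        det = pd.DataFrame({"donor-a": [p], "donor-b": [p]}, index=["p0"])
        calls = call_detection(_matrix(intens, det, ["donor", "donor"]))
        assert bool(calls.present.iloc[0, 0]) is expect

    def test_duplicate_present_filter(self):
        # p0 present in both donor replicates, p1 in only one, p2 nowhere
        intens = pd.DataFrame(np.full((3, 4), 8.0),
                              index=["p0", "p1", "p2"],
                              columns=["donor-a", "donor-b", "t24-a", "t24-b"])
        det = pd.DataFrame(
            [[0.001, 0.001, 0.5, 0.5],
             [0.001, 0.5, 0.5, 0.5],
             [0.5, 0.5, 0.5, 0.5]],
            index=intens.index, columns=intens.columns,
        )
        calls = call_detection(_matrix(intens, det, ["donor", "donor", "t24", "t24"]))
        assert list(calls.analysis_set) == ["p0"]


class TestDifferentialExpression:
    def test_null_contrast_not_regulated(self, toy_matrix):
        m = toy_matrix
        m.intensities[["t24-a", "t24-b"]] = m.intensities[["donor-a", "donor-b"]].to_numpy()
        de = differential_expression(m, call_detection(m), "t24", prior_df=0)
        assert np.allclose(de["log2fc"], 0.0)
        assert not de["regulated"].any()

    def test_matches_hand_computed_pooled_t(self, toy_matrix):
        de = differential_expression(toy_matrix, call_detection(toy_matrix),
                                     "t24", prior_df=0)
        t_ref, lfc_ref = pooled_t(np.array([6.1, 6.9]), np.array([5.0, 5.2]))
        assert de.loc["p0", "log2fc"] == pytest.approx(1.4, abs=1e-12)
        assert de.loc["p0", "t"] == pytest.approx(t_ref, rel=1e-9)

    def test_moderated_equals_pooled_at_zero_prior(self, toy_matrix):
        """prior_df=0 reduces the moderated t to the ordinary pooled t
        to at least 6 significant digits on every probe."""
        de = differential_expression(toy_matrix, call_detection(toy_matrix),
                                     "t24", prior_df=0)
        for pid in toy_matrix.probe_ids:
            x = toy_matrix.intensities.loc[pid, ["t24-a", "t24-b"]].to_numpy()
            y = toy_matrix.intensities.loc[pid, ["donor-a", "donor-b"]].to_numpy()
            t_ref, _ = pooled_t(x, y)
            assert de.loc[pid, "t"] == pytest.approx(t_ref, rel=1e-7)

    def test_regulated_flag_requires_both_thresholds(self):
        rng = np.random.default_rng(1)
        intens = pd.DataFrame(rng.normal(8, 1, size=(200, 4)),
                              columns=["donor-a", "donor-b", "t24-a", "t24-b"])
        intens.iloc[:40, 2:] += rng.uniform(0.3, 2.5, size=(40, 1))
        det = pd.DataFrame(0.001, index=intens.index, columns=intens.columns)
        m = _matrix(intens, det, ["donor", "donor", "t24", "t24"])
        de = differential_expression(m, call_detection(m), "t24")
        expected = (de["p_adj"] < 0.05) & (de["log2fc"].abs() > np.log2(1.5))
        assert (de["regulated"] == expected).all()
        up = de[de["regulated"] & (de["log2fc"] > 0)]
        assert (up["direction"] == "up").all()

    def test_single_replicate_group_rejected(self, toy_matrix):
        m = toy_matrix
        groups = m.groups.copy()
        groups["t24-b"] = "other"
        m2 = ExpressionMatrix(m.intensities, m.detection_p, groups)
        with pytest.raises(ValueError, match=">=2 samples"):
            differential_expression(m2, call_detection(m2), "t24")


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        out = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_against_bruteforce_and_statsmodels(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = adjust_bh(p)
            assert np.allclose(ours, bh_bruteforce(p), atol=1e-12)
            assert np.allclose(ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_bounded(self, ps):
        p = np.array(ps)
        out = adjust_bh(p)
        assert np.all(out >= p - 1e-15) and np.all(out <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


class TestRegulationProfile:
    def _fake(self, flags):
        return pd.DataFrame({"regulated": flags}, index=[f"p{i}" for i in range(len(flags))])

    def test_encoding_and_bound(self):
        results = {
            "t24": self._fake([False, False]),
            "t48": self._fake([True, False]),
            "t72": self._fake([True, False]),
            "iPS": self._fake([True, False]),
            "ES": self._fake([True, False]),
        }
        prof = regulation_profile(results)
        assert prof.tolist() == ["01111", "00000"]
        assert prof.nunique() <= 32

    def test_missing_contrast_errors(self):
        with pytest.raises(KeyError, match="missing"):
            regulation_profile({"t24": self._fake([True])})


class TestPCA:
    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        intens = pd.DataFrame({"a": v, "b": v, "c": rng.normal(size=20)})
        det = pd.DataFrame(0.001, index=intens.index, columns=intens.columns)
        m = _matrix(intens, det, ["g1", "g1", "g2"])
        coords = pca_projection(m)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_leading_axis_matches_eigendecomposition(self):
        intens = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.5, 2.4, 3.1, 4.6]],
            index=["p0", "p1"], columns=list("abcd"),
        )
        det = pd.DataFrame(0.001, index=intens.index, columns=intens.columns)
        m = _matrix(intens, det, ["g"] * 4)
        coords = pca_projection(m)
        X = intens.to_numpy().T
        X = X - X.mean(axis=0)
        w, v = np.linalg.eigh(X.T @ X)
        lead = v[:, np.argmax(w)]
        proj = X @ lead
        ratio = coords["PC1"].to_numpy() / proj
        assert np.allclose(np.abs(ratio), np.abs(ratio[0]), atol=1e-8)
        ev = coords.attrs["explained_variance"]
        assert ev[0] >= ev[1]
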