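"""Count scaling, signature scoring, cycle calls and GO concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idletrace.scores import (
    GeneSignature,
    baseline_log2fc,
    classify_cycle,
    classify_cycle_table,
    go_concordance,
    scale_counts,
    signature_score,
)
from idletrace.synthetic import gen_go_tables


def _matrix(n_genes=60, n_cells=20, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.poisson(5, size=(n_genes, n_cells)) + 1
    return pd.DataFrame(data,
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"c{j}" for j in range(n_cells)])


class TestScaleCounts:
    def test_scale_factors_from_median(self):
        mat = pd.DataFrame({"c1": [100], "c2": [200], "c3": [400]},
                           index=["g"]).astype(float)
        scaled = scale_counts(mat)
        assert scaled.loc["g"].tolist() == [200, 200, 200]

    def test_equal_depth_unchanged(self):
        mat = pd.DataFrame(np.full((4, 3), 2.0))
        assert np.allclose(scale_counts(mat), mat)

    def test_column_sums_equal_median_and_idempotent(self):
        mat = _matrix(seed=1)
        scaled = scale_counts(mat)
        med = mat.sum(axis=0).median()
        assert np.allclose(scaled.sum(axis=0), med)
        assert np.allclose(scale_counts(scaled), scaled)

    def test_zero_total_cell_rejected(self):
        mat = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            scale_counts(mat)


class TestSignatureScore:
    def test_uniform_matrix_scores_zero(self):
        mat = pd.DataFrame(np.full((50, 8), 3.0),
                           index=[f"g{i}" for i in range(50)])
        sig = GeneSignature("s", ("g1", "g2", "g3"))
        assert np.allclose(signature_score(mat, sig, seed=0), 0.0)

    def test_spiked_cells_score_higher(self):
        mat = _matrix(seed=2).astype(float)
        sig_genes = ("g0", "g1", "g2", "g3", "g4")
        spiked = ["c0", "c1", "c2"]
        mat.loc[list(sig_genes), spiked] *= 10
        scores = signature_score(mat, GeneSignature("s", sig_genes), seed=1)
        assert scores[spiked].min() > scores.drop(spiked).max()

    def test_absent_signature_rejected(self):
        with pytest.raises(ValueError):
            signature_score(_matrix(), GeneSignature("s", ("nope",)), seed=0)

    def test_signed_signature_direction(self):
        mat = _matrix(seed=3).astype(float)
        up, down = ("g0", "g1"), ("g2", "g3")
        mat.loc[list(up), ["c0"]] *= 8
        mat.loc[list(down), ["c0"]] /= 8
        sig = GeneSignature("signed", up, down=down)
        scores = signature_score(mat, sig, seed=2)
        assert scores["c0"] > scores.drop("c0").max()

    def test_seed_reproducible(self):
        mat = _matrix(seed=4)
        sig = GeneSignature("s", ("g0", "g5", "g9"))
        a = signature_score(mat, sig, seed=7)
        b = signature_score(mat, sig, seed=7)
        assert a.equals(b)

    def test_permutation_null_centers_on_zero(self):
        # random gene sets: mean score across draws ~ 0
        mat = _matrix(n_genes=100, seed=5)
        rng = np.random.default_rng(8)
        means = []
        for i in range(40):
            genes = tuple(rng.choice(mat.index, 8, replace=False))
            s = signature_score(mat, GeneSignature("r", genes), seed=i)
            means.append(s.mean())
        assert abs(np.mean(means)) < 3 * np.std(means) / np.sqrt(40)


class TestClassifyCycle:
    @pytest.mark.parametrize("s,g2m,expected", [
        (0.5, -0.2, "fast"),
        (-0.2, 0.5, "fast"),
        (-0.1, -0.3, "slow"),
        (0.0, 0.0, "slow"),
    ])
    def test_decision_rule(self, s, g2m, expected):
        assert classify_cycle(s, g2m) == expected

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(9)
        s = pd.Series(rng.normal(0, 1, 50))
        g = pd.Series(rng.normal(0, 1, 50))
        vec = classify_cycle_table(s, g)
        scalar = [classify_cycle(a, b) for a, b in zip(s, g)]
        assert vec.tolist() == scalar


class TestBaselineLog2fc:
    def test_baseline_column_zero_and_quadrupling(self):
        expr = pd.DataFrame({"d0": [10.0, 4.0], "d8": [10.0, 16.0]},
                            index=["g1", "g2"])
        out = baseline_log2fc(expr, "d0", pseudocount=0.0)
        assert np.allclose(out["d0"], 0)
        assert out.loc["g2", "d8"] == pytest.approx(2.0)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(rng.uniform(1, 100, size=(20, 4)),
                            columns=["d0", "d1", "d3", "d8"])
        out = baseline_log2fc(expr, "d0", pseudocount=1.0)
        manual = np.log2((expr.to_numpy() + 1)
                         / (expr["d0"].to_numpy()[:, None] + 1))
        assert np.allclose(out.to_numpy(), manual)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            baseline_log2fc(pd.DataFrame({"d8": [1.0]}), "d0")


class TestGoConcordance:
    def _table(self, pvals):
        return pd.DataFrame({"term": [f"GO:{i}" for i in range(len(pvals))],
                             "pvalue": pvals})

    def test_identical_tables_rho_one(self):
        t = self._table([0.001, 0.01, 0.04, 0.02])
        res = go_concordance(t, t)
        assert res.rho == pytest.approx(1.0)

    def test_rank_reversal_rho_minus_one(self):
        a = self._table([0.001, 0.005, 0.01, 0.04])
        b = self._table([0.04, 0.01, 0.005, 0.001])
        assert go_concordance(a, b).rho == pytest.approx(-1.0)

    def test_insignificant_terms_excluded_before_intersection(self):
        a = self._table([0.001, 0.01, 0.02, 0.3])
        b = self._table([0.002, 0.02, 0.04, 0.001])
        res = go_concordance(a, b, alpha=0.05)
        assert res.n_shared == 3

    def test_too_few_shared_terms_rejected(self):
        a = self._table([0.01, 0.3, 0.4])
        b = self._table([0.02, 0.5, 0.6])
        with pytest.raises(ValueError):
            go_concordance(a, b)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            go_concordance(self._table([0.0, 0.1, 0.2]),
                           self._table([0.1, 0.2, 0.3]))

    @given(st.sampled_from([lambda p: p, lambda p: p ** 2,
                            lambda p: 1 - np.exp(-5 * p)]))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, transform):
        a, b, _ = gen_go_tables(n_terms=50, n_shared=40, rho=0.6, seed=11)
        base = go_concordance(a, b).rho
        # strictly monotone transforms preserve ranks, hence rho;
        # scale back into (0, alpha) so the filter keeps the same terms
        a2 = a.copy()
        a2["pvalue"] = transform(a2["pvalue"].to_numpy()) * 0.049 + 1e-12
        assert go_concordance(a2, b).rho == pytest.approx(base, abs=1e-9)

    def test_null_tables_rarely_correlated(self):
        hits = 0
        for s in range(40):
            a, b, _ = gen_go_tables(n_terms=220, n_shared=200, rho=0.0,
                                    seed=s)
            if abs(go_concordance(a, b).rho) >= 0.2:
                hits += 1
        assert hits <= 2  # |rho| < 0.2 in at least 95% of null draws
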