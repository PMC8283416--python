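"""Correspondence analysis against an independent oracle; Spearman matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import svd as scipy_svd

from cubkit.genetics import SYNONYMOUS_CODONS
from cubkit.multivariate import correspondence_analysis, spearman_matrix
from cubkit.rscu import compute_rscu
from cubkit.sequence_io import count_codons
from cubkit.synthetic import GeneratorConfig, generate_panel


def ca_oracle(X: np.ndarray):
    """Textbook CA coded independently: explicit diagonal-matrix products
    around scipy's SVD.  Returns (row principal coords, col principal
    coords, singular values)."""
    n = X.sum()
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Dr_isqrt = np.diag(1.0 / np.sqrt(r))
    Dc_isqrt = np.diag(1.0 / np.sqrt(c))
    S = Dr_isqrt @ (P - np.outer(r, c)) @ Dc_isqrt
    U, sv, Vt = scipy_svd(S, full_matrices=False)
    rank = min(X.shape) - 1
    U, sv, Vt = U[:, :rank], sv[:rank], Vt[:rank, :]
    F = Dr_isqrt @ U * sv
    G = Dc_isqrt @ Vt.T * sv
    return F, G, sv


def _align_signs(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Flip columns of B so each correlates positively with A's (sign freedom)."""
    signs = np.sign(np.sum(A * B, axis=0))
    signs[signs == 0] = 1.0
    return B * signs


class TestCorrespondenceAnalysis:
    def test_identical_rows_zero_inertia(self):
        X = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (5, 1))
        res = correspondence_analysis(X, k=2)
        assert res.total_inertia == 0.0
        assert (res.row_coords.to_numpy() == 0).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.1, 5.0, size=(6, 10))
        res = correspondence_analysis(X, k=5)
        F, G, sv = ca_oracle(X)
        got_rows = res.row_coords.to_numpy()
        got_cols = res.col_coords.to_numpy()
        k = got_rows.shape[1]
        np.testing.assert_allclose(
            got_rows, _align_signs(got_rows, F[:, :k]), atol=1e-9)
        np.testing.assert_allclose(
            got_cols, _align_signs(got_cols, G[:, :k]), atol=1e-9)
        np.testing.assert_allclose(
            res.inertia_fractions, sv**2 / (sv**2).sum(), atol=1e-12)

    def test_total_inertia_is_chisquare_over_total(self):
        rng = np.random.default_rng(99)
        X = rng.integers(1, 40, size=(7, 9)).astype(float)
        res = correspondence_analysis(X)
        chi2 = stats.chi2_contingency(X, correction=False).statistic
        assert res.total_inertia == pytest.approx(chi2 / X.sum(), rel=1e-9)

    def test_scale_invariance_of_coordinates(self):
        rng = np.random.default_rng(41)
        X = rng.uniform(0.5, 3.0, size=(5, 8))
        a = correspondence_analysis(X, k=3)
        b = correspondence_analysis(7.5 * X, k=3)
        pd.testing.assert_frame_equal(a.row_coords, b.row_coords)

    def test_inertia_fractions_sum_to_one(self):
        rng = np.random.default_rng(43)
        X = rng.uniform(0.1, 2.0, size=(6, 6))
        res = correspondence_analysis(X, k=5)
        assert res.inertia_fractions.sum() == pytest.approx(1.0)

    def test_all_zero_column_dropped(self):
        rng = np.random.default_rng(44)
        X = rng.uniform(0.5, 2.0, size=(4, 5))
        X[:, 2] = 0.0
        res = correspondence_analysis(X, k=2)
        assert "col2" not in res.col_coords.index

    def test_three_selection_targets_separate_into_clusters(self):
        """Strain groups generated toward three distinct RSCU targets form
        three clusters on the first two CA axes (silhouette > 0.5)."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(7)
        groups = []
        for gname in ("g1", "g2", "g3"):
            vals = {}
            for codons in _families():
                p = rng.dirichlet(np.full(len(codons), 0.3))
                for c, pi in zip(codons, p):
                    vals[c] = pi * len(codons)
            from cubkit.rscu import RSCUVector

            groups.append((gname, {"selection_target": RSCUVector(values=vals),
                                   "selection_weight": 0.9}))
        cfg = GeneratorConfig(n_strains=30, segments={"WG": 400},
                              mutation_gc3=0.31, groups=groups, seed=17)
        seqs, meta = generate_panel(cfg)
        mat = pd.DataFrame(
            [np.nan_to_num(compute_rscu(count_codons(s)).as_list()) for s in seqs],
            columns=list(SYNONYMOUS_CODONS))
        res = correspondence_analysis(mat, k=2)
        labels = [s.clade for s in seqs]
        score = silhouette_score(res.row_coords.to_numpy(), labels)
        assert score > 0.5


def _families():
    from cubkit.genetics import AA_TO_CODONS, DEGENERATE_AAS

    return [AA_TO_CODONS[aa] for aa in DEGENERATE_AAS]


class TestSpearmanMatrix:
    def test_perfect_concordance_and_discordance(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "up": 2 * x + 1, "down": -x})
        m = spearman_matrix(df)
        assert m.rho.loc["x", "up"] == pytest.approx(1.0)
        assert m.rho.loc["x", "down"] == pytest.approx(-1.0)
        assert (np.diag(m.rho) == 1.0).all()

    def test_tied_ranks_average_rank_formula(self):
        # x: 1 2 3 4 5; y: 1 1 3 4 5 -> average ranks (1.5, 1.5, 3, 4, 5)
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 1, 3, 4, 5])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        m = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        assert m.rho.loc["x", "y"] == pytest.approx(expected)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        m = spearman_matrix(df)
        pd.testing.assert_frame_equal(m.rho, m.rho.T)

    def test_constant_variable_flagged_nan(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "const": [5.0, 5, 5, 5]})
        m = spearman_matrix(df)
        assert np.isnan(m.rho.loc["x", "const"])

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"x": [1.0, 2], "y": [3.0, 4]}))
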