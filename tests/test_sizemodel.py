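import numpy as np
import pytest
from scipy import stats

from lcmseq.quantify import to_rpm
from lcmseq.simulate import SimConfig, gen_oocyte_cohort, logistic_level
from lcmseq.sizemodel import (
    average_zscore_profile,
    build_size_model,
    fit_pca,
    fit_sigmoid,
    fit_size_model,
    gene_diameter_correlations,
    match_oocytes,
    pc_diameter_association,
    top_loading_genes,
)


def eigen_pca_oracle(X: np.ndarray):
    """Independent PCA via eigendecomposition of the gene covariance.

    X is genes x cells; returns (mean, loadings, scores) with the same
    largest-entry-positive sign convention.
    """
    mu = X.mean(axis=1)
    C = (X - mu[:, None]) @ (X - mu[:, None]).T  # gene x gene scatter
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    scores = (X - mu[:, None]).T @ v
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] *= -1
            scores[:, j] *= -1
    return mu, v, scores


class TestFitPca:
    def test_rank_one_data(self):
        d = np.linspace(1, 10, 6)
        X = np.vstack([2 * d + 5, 4 * d + 5, -3 * d + 20])
        pca = fit_pca(X, ["a", "b", "c"], min_log2=0)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(6, 1, size=(3, 3))
        pca = fit_pca(X, ["a", "b", "c"], min_log2=0)
        mu, v, scores = eigen_pca_oracle(X)
        np.testing.assert_allclose(pca.mean_log2, mu, atol=1e-10)
        k = pca.loadings.shape[1]
        np.testing.assert_allclose(np.abs(pca.loadings), np.abs(v[:, :k]), atol=1e-10)
        np.testing.assert_allclose(pca.loadings, v[:, :k], atol=1e-10)
        np.testing.assert_allclose(pca.scores, scores[:, :k], atol=1e-10)

    def test_filter_rule_excludes_low_genes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(6, 1, size=(5, 4))
        low = np.full((1, 4), 3.0)  # never exceeds the floor
        pca_with = fit_pca(np.vstack([X, low]), list("abcdeL"), min_log2=4)
        pca_without = fit_pca(X, list("abcde"), min_log2=4)
        assert pca_with.gene_ids == pca_without.gene_ids
        np.testing.assert_allclose(pca_with.loadings, pca_without.loadings)

    def test_full_rank_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(6, 1, size=(8, 5))
        pca = fit_pca(X, [f"g{i}" for i in range(8)], min_log2=0)
        recon = pca.mean_log2[:, None] + pca.loadings @ pca.scores.T
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(6, 1, size=(10, 6))
        pca = fit_pca(X, [f"g{i}" for i in range(10)], min_log2=0)
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.normal(6, 1, size=(10, 6))
        p1 = fit_pca(X, [f"g{i}" for i in range(10)], min_log2=0)
        p2 = fit_pca(X.copy(), [f"g{i}" for i in range(10)], min_log2=0)
        np.testing.assert_array_equal(p1.loadings, p2.loadings)
        np.testing.assert_array_equal(p1.scores, p2.scores)

    def test_filter_leaves_too_few(self):
        with pytest.raises(ValueError, match="filter"):
            fit_pca(np.ones((3, 4)), list("abc"), min_log2=4)


class TestPcDiameterAssociation:
    def test_perfect_negative(self):
        d = np.array([20.0, 30, 40, 50])
        scores = (-d)[:, None]
        rs = pc_diameter_association(scores, d)
        assert rs[0] == pytest.approx(-1.0)

    def test_permutation_null_centered(self):
        rng = np.random.default_rng(0)
        d = np.linspace(20, 80, 30)
        vals = []
        for _ in range(200):
            perm = rng.permutation(d)
            vals.append(pc_diameter_association(perm[:, None], d)[0])
        assert abs(np.mean(vals)) < 0.05

    def test_ties_match_brute_force_oracle(self):
        # average-rank Spearman on a 6-cell fixture with tied diameters
        d = np.array([20.0, 20.0, 40.0, 40.0, 60.0, 80.0])
        s = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])

        def avg_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            i = 0
            sx = x[order]
            while i < len(x):
                j = i
                while j < len(x) and sx[j] == sx[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        r1, r2 = avg_ranks(s), avg_ranks(d)
        oracle = np.corrcoef(r1, r2)[0, 1]
        rs = pc_diameter_association(s[:, None], d)[0]
        assert rs == pytest.approx(oracle, abs=1e-12)


class TestGeneDiameterCorrelations:
    def test_linear_gene_in_positive_set(self):
        d = np.linspace(20, 80, 10)
        X = np.vstack([d * 0.1, np.full(10, 5.0)])
        corr = gene_diameter_correlations(X, ["lin", "const"], d)
        assert corr.r["lin"] == pytest.approx(1.0)
        assert "lin" in corr.positive
        assert "const" not in corr.r.index  # zero variance excluded

    def test_sets_disjoint(self):
        rng = np.random.default_rng(0)
        d = np.linspace(20, 80, 20)
        X = rng.normal(5, 1, size=(50, 20))
        corr = gene_diameter_correlations(X, [f"g{i}" for i in range(50)], d)
        assert not (set(corr.positive) & set(corr.negative))

    def test_planted_sigmoids_recovered(self, fast_sim):
        # low-noise setting: steep high-amplitude rising genes land in the
        # positively correlated set
        cfg = SimConfig(**{**fast_sim.__dict__, "noise_sd": 0.2, "n_retarded": 0})
        m, recs, truth = gen_oocyte_cohort(cfg, 7)
        log2 = to_rpm(m).log2
        d = np.array([r.diameter_um for r in recs])
        corr = gene_diameter_correlations(log2, m.gene_ids, d)
        classes = np.array(truth.gene_classes)
        amp = np.array(truth.upper) - np.array(truth.lower)
        k = np.array(truth.steepness)
        lo = np.array(truth.lower)
        d0 = np.array(truth.inflection_um)
        strong = (
            (classes == "rising-sigmoid") & (amp > 4.5) & (k > 0.1)
            & (lo > 2.0) & (d0 > 35) & (d0 < 65)
        )
        ids = [m.gene_ids[i] for i in np.where(strong)[0]]
        assert len(ids) >= 5
        in_pos = np.mean([g in corr.positive for g in ids])
        assert in_pos >= 0.9

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            gene_diameter_correlations(np.ones((3, 5)), list("abc"), np.arange(5.0))


class TestAverageZscore:
    def test_single_gene_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 2, size=(3, 8))
        prof = average_zscore_profile(X, ["a", "b", "c"], ["b"])
        z = (X[1] - X[1].mean()) / X[1].std()
        np.testing.assert_allclose(prof, z)

    def test_mean_over_cells_is_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 2, size=(10, 8))
        prof = average_zscore_profile(X, [f"g{i}" for i in range(10)],
                                      [f"g{i}" for i in range(10)])
        assert abs(prof.mean()) < 1e-10

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            average_zscore_profile(np.ones((2, 3)), ["a", "b"], [])


class TestFitSigmoid:
    def test_exact_recovery(self):
        d = np.linspace(20, 80, 44)
        y = logistic_level(d, np.array(-1.0), np.array(1.0), np.array(0.3),
                           np.array(45.0))
        fit = fit_sigmoid(d, y)
        assert fit.inflection_um == pytest.approx(45.0, abs=1e-6)
        assert fit.lower == pytest.approx(-1.0, abs=1e-5)
        assert fit.upper == pytest.approx(1.0, abs=1e-5)
        assert fit.converged

    def test_noisy_recovery(self):
        hits = 0
        for s in range(25):
            rng = np.random.default_rng(s)
            d = np.sort(rng.uniform(20, 80, 44))
            y = logistic_level(d, np.array(-1.0), np.array(1.0), np.array(0.3),
                               np.array(45.0)) + rng.normal(0, 0.1, 44)
            fit = fit_sigmoid(d, y)
            hits += abs(fit.inflection_um - 45.0) <= 3.0
        assert hits >= 24

    def test_constant_input(self):
        d = np.linspace(20, 80, 10)
        fit = fit_sigmoid(d, np.full(10, 2.5))
        assert fit.steepness == 0.0
        assert fit.rss == 0.0

    def test_falling_curve(self):
        d = np.linspace(20, 80, 30)
        y = logistic_level(d, np.array(3.0), np.array(1.0), np.array(0.25),
                           np.array(50.0))
        fit = fit_sigmoid(d, y)
        assert fit.inflection_um == pytest.approx(50.0, abs=1e-4)
        assert fit.lower > fit.upper  # falling: high early asymptote

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_sigmoid(np.arange(4.0), np.arange(4.0))


class TestSizeModel:
    def _toy_pca(self):
        # scores exactly linear in diameter, 5 cells, 4 genes
        d = np.array([20.0, 35.0, 50.0, 65.0, 80.0])
        L = np.linalg.qr(np.random.default_rng(0).normal(size=(4, 2)))[0]
        scores = np.stack([2.0 + 0.5 * d, -1.0 + 0.1 * d], axis=1)
        mu = np.array([50.0, 60.0, 40.0, 70.0])  # keep all genes above the filter
        X = mu[:, None] + L @ scores.T
        pca = fit_pca(X, list("abcd"), min_log2=0)
        return X, d, pca

    def test_default_grid_bins(self):
        X, d, pca = self._toy_pca()
        model = fit_size_model(pca, d)
        np.testing.assert_allclose(model.grid_um, np.arange(10.0, 101.0, 10.0))
        assert model.reconstruction.shape == (4, 10)

    def test_zero_loadings_reconstruct_mean(self):
        X, d, pca = self._toy_pca()
        pca.loadings = np.zeros_like(pca.loadings[:, :2])
        pca.scores = pca.scores[:, :2]
        pca.explained_variance_ratio = pca.explained_variance_ratio[:2]
        model = fit_size_model(pca, d)
        for col in model.reconstruction.T:
            np.testing.assert_allclose(col, pca.mean_log2)

    def test_linear_scores_reconstruct_training_cells(self):
        # noise-free rank-2 data: reconstruction at a training diameter
        # equals that cell's profile (matrix-algebra oracle)
        X, d, pca = self._toy_pca()
        model = fit_size_model(pca, d, grid_um=d)
        np.testing.assert_allclose(model.reconstruction, X, atol=1e-8)

    def test_zero_diameter_variance_rejected(self):
        X, d, pca = self._toy_pca()
        with pytest.raises(ValueError):
            fit_size_model(pca, np.full(5, 50.0))


class TestMatchOocytes:
    def test_self_match(self):
        X, d, pca = TestSizeModel()._toy_pca()
        model = fit_size_model(pca, d)
        # cell whose profile equals the reconstruction at 50 um
        target = model.reconstruction[:, model.grid_um == 50.0].ravel()
        res = match_oocytes(
            target[:, None], model.gene_ids, ["cell"], np.array([62.0]), model
        )
        row = res.table.iloc[0]
        assert row["best_match_um"] == 50.0
        assert row["best_rs"] == pytest.approx(1.0)
        assert row["delta_um"] == pytest.approx(12.0)
        assert not row["retarded"]

    def test_tie_goes_to_smaller_bin(self):
        X, d, pca = TestSizeModel()._toy_pca()
        model = fit_size_model(pca, d)
        model.reconstruction[:, 1] = model.reconstruction[:, 0]  # force a tie
        target = model.reconstruction[:, 0]
        res = match_oocytes(
            target[:, None], model.gene_ids, ["cell"], np.array([10.0]), model
        )
        assert res.table.iloc[0]["best_match_um"] == model.grid_um[0]
        assert res.table.iloc[0]["tied"]

    def test_gene_list_mismatch_rejected(self):
        X, d, pca = TestSizeModel()._toy_pca()
        model = fit_size_model(pca, d)
        with pytest.raises(ValueError, match="gene list"):
            match_oocytes(X, ["w", "x", "y", "z"], list("pqrst"), d, model)

    def test_retardation_flagged_on_simulation(self, fast_sim):
        m, recs, truth = gen_oocyte_cohort(fast_sim, 11)
        expr = to_rpm(m)
        d = np.array([r.diameter_um for r in recs])
        model, match = build_size_model(expr.log2, expr.gene_ids, expr.cell_ids, d)
        ret = np.array(truth.retarded)
        assert match.table["retarded"].to_numpy()[ret].all()
        assert match.table["retarded"].to_numpy()[~ret].sum() <= 1
        # retarded implies deviant
        assert (
            match.table["deviant"] | ~match.table["retarded"]
        ).all()


class TestTopLoadingGenes:
    def _signed_pca(self):
        # loadings with both signs on each component
        d = np.array([20.0, 35.0, 50.0, 65.0, 80.0])
        L = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]]) / 2.0
        scores = np.stack([2.0 + 0.5 * d, -1.0 + 0.1 * d], axis=1)
        mu = np.array([50.0, 60.0, 40.0, 70.0])
        X = mu[:, None] + L @ scores.T
        return fit_pca(X, list("abcd"), min_log2=0)

    def test_single_gene_lists(self):
        pca = self._signed_pca()
        pos, neg = top_loading_genes(pca, n=1, component=1)
        load = pca.loadings[:, 1]
        assert pos[0] == pca.gene_ids[int(np.argmax(load))]
        assert neg[0] == pca.gene_ids[int(np.argmin(load))]
        assert set(pos).isdisjoint(neg)

    def test_requesting_too_many(self):
        pca = self._signed_pca()
        with pytest.raises(ValueError):
            top_loading_genes(pca, n=10, component=1)

    def test_sigmoid_classes_split_by_sign(self, fast_sim):
        m, recs, truth = gen_oocyte_cohort(fast_sim, 13)
        expr = to_rpm(m)
        pca = fit_pca(expr.log2, expr.gene_ids, expr.cell_ids)
        classes = dict(zip(m.gene_ids, truth.gene_classes))
        d = np.array([r.diameter_um for r in recs])
        # orient along the diameter axis using PC1 (dominant here)
        rs = pc_diameter_association(pca.scores[:, :1], d)[0]
        n = 40
        pos, neg = top_loading_genes(pca, n=n, component=0)
        up_list, down_list = (pos, neg) if rs > 0 else (neg, pos)
        frac_rising = np.mean([classes[g] == "rising-sigmoid" for g in up_list])
        frac_falling = np.mean([classes[g] == "falling-sigmoid" for g in down_list])
        assert frac_rising >= 0.8
        assert frac_falling >= 0.8
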