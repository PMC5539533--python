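import numpy as np
import pytest

from fiberspec import (
    SyntheticConfig,
    fit_pca,
    generate_dataset,
    loo_cross_validation,
    pca_pretreat,
    scores_vs_dpa,
)
from fiberspec.preprocess import PreprocessConfig, preprocess_sample, savgol_first_derivative


class TestPretreat:
    def test_column_means_are_zero(self, tiny_config):
        dataset, _ = generate_dataset(tiny_config)
        matrix, wn = pca_pretreat(dataset)
        assert np.allclose(matrix.mean(axis=0), 0.0, atol=1e-12)
        assert matrix.shape == (len(dataset), wn.size)
        assert wn.min() >= 600.0 and wn.max() <= 1800.0

    def test_identical_samples_give_zero_matrix(self):
        import dataclasses

        cfg = SyntheticConfig(
            dpa_list=(24,), genotypes=("TM-1",), replicates=3, scans_per_sample=1
        ).noise_free()
        dataset, _ = generate_dataset(cfg)
        matrix, _ = pca_pretreat(dataset)
        assert np.allclose(matrix, 0.0, atol=1e-12)

    def test_matches_stepwise_oracle(self, tiny_config):
        dataset, _ = generate_dataset(tiny_config)
        cfg = PreprocessConfig()
        matrix, wn = pca_pretreat(dataset, cfg)
        rows = []
        for sample in dataset:
            norm = preprocess_sample(sample, cfg)[1]
            rows.append(
                savgol_first_derivative(norm.absorbance, norm.wavenumbers)[0]
            )
        oracle = np.vstack(rows)
        oracle -= oracle.mean(axis=0)
        assert np.allclose(matrix, oracle, atol=1e-12)

    def test_needs_two_samples(self):
        cfg = SyntheticConfig(dpa_list=(24,), genotypes=("TM-1",), replicates=1)
        dataset, _ = generate_dataset(cfg)
        with pytest.raises(ValueError, match=">=2"):
            pca_pretreat(dataset)


class TestFitPCA:
    def test_two_samples_are_rank_one(self):
        rng = np.random.default_rng(0)
        matrix = rng.normal(size=(2, 10))
        model = fit_pca(matrix, 1)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_fractions_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(9)
        matrix = rng.normal(size=(6, 20))
        model = fit_pca(matrix, 5)
        centered = matrix - matrix.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(centered @ centered.T))[::-1]
        oracle = eigvals[:5] / eigvals.sum()
        assert np.allclose(model.explained_variance_fraction, oracle, atol=1e-8)

    def test_scores_and_loadings_reconstruct_centered_matrix(self):
        rng = np.random.default_rng(2)
        matrix = rng.normal(size=(6, 12))
        model = fit_pca(matrix, 5)  # full rank for 6 samples
        centered = matrix - matrix.mean(axis=0)
        assert np.allclose(model.scores @ model.loadings, centered, atol=1e-9)

    def test_loadings_orthonormal_scores_orthogonal_fractions_monotone(self):
        rng = np.random.default_rng(4)
        model = fit_pca(rng.normal(size=(10, 30)), 6)
        assert np.allclose(model.loadings @ model.loadings.T, np.eye(6), atol=1e-9)
        gram = model.scores.T @ model.scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        frac = model.explained_variance_fraction
        assert (np.diff(frac) <= 1e-12).all() and frac.sum() <= 1 + 1e-12
        assert np.allclose(model.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(6)
        row_pool = rng.normal(size=(4, 15))
        matrix = np.vstack([row_pool, row_pool[1]])
        model = fit_pca(matrix, 3)
        assert np.allclose(model.scores[1], model.scores[4], atol=1e-9)

    def test_sample_reordering_invariance_up_to_sign(self):
        rng = np.random.default_rng(8)
        matrix = rng.normal(size=(7, 11))
        perm = rng.permutation(7)
        m1 = fit_pca(matrix, 3)
        m2 = fit_pca(matrix[perm], 3)
        for k in range(3):
            dot = abs(np.dot(m1.loadings[k], m2.loadings[k]))
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_orientation_follows_dpa(self):
        rng = np.random.default_rng(10)
        dpa = np.repeat([10, 24, 37, 44], 2)
        latent = (dpa - 10) / 34.0
        matrix = np.outer(latent, rng.normal(size=9)) + 0.01 * rng.normal(size=(8, 9))
        model = fit_pca(matrix, 2, dpa=dpa)
        rho = np.corrcoef(model.scores[:, 0], dpa)[0, 1]
        assert rho > 0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_pca(np.ones((4, 5)), 2)
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(np.random.default_rng(0).normal(size=(3, 5)), 3)


class TestLOOCrossValidation:
    def test_rank_one_matrix_has_zero_press_at_k1(self):
        u = np.linspace(0, 1, 6)
        v = np.arange(1.0, 9.0)
        matrix = np.outer(u, v)
        press = loo_cross_validation(matrix, 2)
        assert press[0] == pytest.approx(0.0, abs=1e-18)

    def test_press_non_negative_and_matches_brute_force(self):
        rng = np.random.default_rng(13)
        matrix = rng.normal(size=(5, 8))
        press = loo_cross_validation(matrix, 3)
        assert (press >= 0).all()

        oracle = np.zeros(3)
        for i in range(5):
            train = np.vstack([matrix[j] for j in range(5) if j != i])
            mu = train.mean(axis=0)
            cov = (train - mu).T @ (train - mu)
            w, v = np.linalg.eigh(cov)
            order = np.argsort(w)[::-1]
            v = v[:, order]
            resid = matrix[i] - mu
            for k in range(1, 4):
                vk = v[:, :k]
                recon = vk @ (vk.T @ resid)
                oracle[k - 1] += np.sum((resid - recon) ** 2)
        assert np.allclose(press, oracle, atol=1e-9)

    def test_range_errors(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match=">=3"):
            loo_cross_validation(rng.normal(size=(2, 4)), 1)
        with pytest.raises(ValueError, match="max_components"):
            loo_cross_validation(rng.normal(size=(4, 4)), 4)


class TestScoresVsDPA:
    def test_table_shape_and_centering(self, tiny_config):
        dataset, _ = generate_dataset(tiny_config)
        matrix, _ = pca_pretreat(dataset)
        dpa = np.array([s.dpa for s in dataset])
        model = fit_pca(matrix, 3, dpa=dpa)
        table = scores_vs_dpa(model, dataset)
        assert len(table) == len(dataset)
        assert list(table.columns[:4]) == ["sample_id", "genotype", "dpa", "replicate"]
        assert table["pc1_score"].mean() == pytest.approx(0.0, abs=1e-9)
        assert (table["dpa"].diff().dropna() >= 0).all()  # single genotype

    def test_sample_count_mismatch_raises(self, tiny_config):
        dataset, _ = generate_dataset(tiny_config)
        matrix, _ = pca_pretreat(dataset)
        model = fit_pca(matrix[:-2], 2)
        with pytest.raises(ValueError, match="samples"):
            scores_vs_dpa(model, dataset)

    def test_realistic_mode_pc1_rises_early_then_plateaus(self):
        cfg = SyntheticConfig(latent_mode="realistic").noise_free()
        dataset, _ = generate_dataset(cfg)
        matrix, _ = pca_pretreat(dataset)
        dpa = np.array([s.dpa for s in dataset])
        model = fit_pca(matrix, 2, dpa=dpa)
        table = scores_vs_dpa(model, dataset)
        mean_pc1 = table.groupby("dpa")["pc1_score"].mean()
        early_rise = mean_pc1[24] - mean_pc1[10]
        late_rise = mean_pc1[44] - mean_pc1[24]
        assert early_rise > late_rise > 0
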