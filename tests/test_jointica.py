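import numpy as np
import pandas as pd
import pytest

import mirmix as mm
from mirmix import jointica
from conftest import make_matrix


def log_matrix(values, kind="mRNA-gene", prefix="g"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{i}" for i in range(values.shape[1])],
    )
    return mm.ExpressionMatrix(df, "log2", kind)


class TestDimensionEstimate:
    def test_iid_gaussian_has_no_structure(self):
        # pure-noise matrices should rarely clear the Marchenko-Pastur edge
        estimates = [
            mm.estimate_num_components(
                log_matrix(np.random.default_rng(s).standard_normal((500, 60)))
            )
            for s in range(20)
        ]
        assert max(estimates) <= 3

    def test_planted_rank_three(self):
        rng = np.random.default_rng(5)
        C = rng.standard_normal((500, 3)) * 10
        M = rng.standard_normal((3, 60))
        X = C @ M + rng.standard_normal((500, 60))
        assert mm.estimate_num_components(log_matrix(X)) == 3

    def test_cap_at_samples_minus_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 2)) * 10
        assert mm.estimate_num_components(log_matrix(X)) <= 1

    def test_constant_matrix_zero(self):
        assert mm.estimate_num_components(log_matrix(np.ones((20, 10)))) == 0

    def test_joint_dimension_is_max(self, log_views):
        mrna, mirna = log_views
        est = mm.choose_joint_dimension(mrna, mirna)
        assert est == max(
            mm.estimate_num_components(mrna), mm.estimate_num_components(mirna)
        )
        assert mm.choose_joint_dimension(mrna, mrna) == mm.estimate_num_components(mrna)


class TestWhitening:
    def test_whitening_contract(self, log_views):
        mrna, _ = log_views
        X, K = mm.whiten_view(mrna, 4)
        G = X.shape[0]
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(X.T @ X / (G - 1), np.eye(4), atol=1e-8)

    def test_duplicated_rows_identical(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((30, 12))
        dup = np.vstack([base, base[:3]])
        X, _ = mm.whiten_view(log_matrix(dup), 3)
        # rows are affine in the original rows, so duplicates stay duplicates
        np.testing.assert_allclose(X[30:], X[:3], atol=1e-10)

    def test_too_many_components(self, log_views):
        _, mirna = log_views
        with pytest.raises(ValueError):
            mm.whiten_view(mirna, mirna.n_samples + 1)


class TestJointFit:
    def test_degenerate_single_view_recovers_sources(self):
        # two planted independent non-Gaussian sources, second view = copy
        rng = np.random.default_rng(11)
        C = np.column_stack(
            [rng.laplace(size=800), rng.uniform(-1, 1, size=800)]
        )
        M = rng.standard_normal((2, 40))
        E = log_matrix(C @ M + 0.1 * rng.standard_normal((800, 40)))
        E2 = mm.ExpressionMatrix(E.data.copy(), "log2", "miRNA-strand")
        model = mm.fit_joint_ica(E, E2, 2, seed=0)
        corr = jointica.abs_spearman_matrix(C, model.C_m.to_numpy())
        assert (corr.max(axis=1) >= 0.95).all()

    def test_two_view_recovery(self, bundle, log_views):
        mrna, mirna = log_views
        model = mm.fit_joint_ica(mrna, mirna, 3, seed=7)
        truth_m = bundle.truth.C_m.loc[mrna.feature_ids].to_numpy()
        truth_mi = bundle.truth.C_mi.loc[mirna.feature_ids].to_numpy()
        m_match = jointica.abs_spearman_matrix(truth_m, model.C_m.to_numpy()).max(axis=1)
        mi_match = jointica.abs_spearman_matrix(truth_mi, model.C_mi.to_numpy()).max(axis=1)
        assert (m_match >= 0.9).all()
        assert (mi_match >= 0.9).all()

    def test_same_seed_bit_identical(self, log_views):
        mrna, mirna = log_views
        m1 = mm.fit_joint_ica(mrna, mirna, 3, seed=42)
        m2 = mm.fit_joint_ica(mrna, mirna, 3, seed=42)
        assert np.array_equal(m1.W, m2.W)
        assert m1.C_m.equals(m2.C_m) and m1.M_mi.equals(m2.M_mi)

    def test_stacked_columns_standardized_w_orthonormal(self, fitted_model):
        C = fitted_model.C_stacked
        np.testing.assert_allclose(C.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(C.var(axis=0, ddof=1), 1, atol=1e-10)
        W = fitted_model.W
        np.testing.assert_allclose(W.T @ W, np.eye(W.shape[1]), atol=1e-6)

    def test_repression_sign_structure(self, bundle, log_views):
        """Planted miRNAs and their targets load with opposite signs."""
        mrna, mirna = log_views
        model = mm.fit_joint_ica(mrna, mirna, 3, seed=7)
        truth_mi = bundle.truth.C_mi.loc[mirna.feature_ids].to_numpy()
        k = jointica.abs_spearman_matrix(truth_mi, model.C_mi.to_numpy()).argmax(axis=1)[0]
        mirs = [m for m in bundle.truth.mir_seqs if m in model.C_mi.index]
        mir_sign = np.sign(model.C_mi.loc[mirs, k].mean())
        targets = [
            g for gs in bundle.truth.target_map.values() for g in gs
            if g in model.C_m.index
        ]
        opposite = (np.sign(model.C_m.loc[targets, k]) == -mir_sign).mean()
        assert opposite >= 0.8


class TestMixing:
    def test_reconstruction_near_pca_truncation(self, fitted_model, log_views):
        mrna, _ = log_views
        Ec = jointica._double_center(mrna.values)
        recon = fitted_model.C_m.to_numpy() @ fitted_model.M_m.to_numpy()
        _, s, _ = np.linalg.svd(Ec, full_matrices=False)
        pca_resid = np.sqrt((s[3:] ** 2).sum())
        assert np.linalg.norm(Ec - recon) <= pca_resid * 1.0001

    def test_noiseless_low_rank_exact(self):
        rng = np.random.default_rng(2)
        C = np.column_stack([rng.laplace(size=300), rng.uniform(-1, 1, 300)])
        M = rng.standard_normal((2, 20))
        E = log_matrix(C @ M)
        E2 = log_matrix(rng.laplace(size=(80, 20)) @ np.eye(20), prefix="h")
        # second view also exactly rank-limited through the same M
        C2 = np.column_stack([rng.laplace(size=80), rng.uniform(-1, 1, 80)])
        E2 = log_matrix(C2 @ M, prefix="h")
        model = mm.fit_joint_ica(E, E2, 2, seed=0)
        Ec = jointica._double_center(E.values)
        recon = model.C_m.to_numpy() @ model.M_m.to_numpy()
        np.testing.assert_allclose(recon, Ec, atol=1e-8)

    def test_scale_invariance_fixed_by_unit_variance(self, fitted_model):
        # C columns have unit variance, M absorbs all scale: rescaling any
        # column and the matching M row leaves the product unchanged
        C = fitted_model.C_m.to_numpy().copy()
        M = fitted_model.M_m.to_numpy().copy()
        prod = C @ M
        C[:, 0] *= 3.0
        M[0] /= 3.0
        np.testing.assert_allclose(C @ M, prod, atol=1e-10)
        np.testing.assert_allclose(
            fitted_model.C_stacked.std(axis=0, ddof=1), 1.0, atol=1e-10
        )


class TestStability:
    def test_planted_components_stable(self, log_views):
        mrna, mirna = log_views
        model = mm.stability_analysis(mrna, mirna, 3, runs=5, base_seed=0)
        assert (model.stability >= 0.9).all()
        assert (np.diff(model.stability) <= 1e-12).all()  # sorted descending

    def test_surplus_components_less_stable(self, log_views):
        mrna, mirna = log_views
        model = mm.stability_analysis(mrna, mirna, 5, runs=5, base_seed=0)
        # 3 planted sources: the 2 surplus components rank strictly below
        assert model.stability[:3].min() > model.stability[3:].max()

    def test_single_run_rejected(self, log_views):
        mrna, mirna = log_views
        with pytest.raises(ValueError):
            mm.stability_analysis(mrna, mirna, 3, runs=1)

    def test_model_round_trip(self, tmp_path, fitted_model):
        fitted_model.save(tmp_path / "model")
        C_m = pd.read_csv(tmp_path / "model" / "C_m.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(C_m.to_numpy(), fitted_model.C_m.to_numpy())


class TestSignificantFeatures:
    def test_hand_sd_threshold(self):
        w = pd.Series([0.1, 0.2, 3.0], index=list("abc"))
        # SD of |weights| = 1.6462...; only |3.0| clears alpha=1
        sel = mm.significant_features(w, alpha=1.0)
        assert list(sel.features.index) == ["c"]
        assert sel.features["c"] == 1

    def test_alpha_zero_selects_all(self):
        w = pd.Series([0.1, -0.2, 3.0], index=list("abc"))
        sel = mm.significant_features(w, alpha=0.0)
        assert len(sel.features) == 3
        assert sel.negative == ["b"]

    def test_degenerate_equal_weights(self):
        w = pd.Series([0.5, -0.5, 0.5], index=list("abc"))
        sel = mm.significant_features(w, alpha=3.0)
        assert len(sel.features) == 3  # SD of |w| is 0: all selected, flagged

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            mm.significant_features(pd.Series([1.0]), alpha=-1)
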