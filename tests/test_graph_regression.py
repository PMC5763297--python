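import numpy as np
import pytest

from gruf.containers import LdaMatrix, SimilarityMatrix
from gruf.graph_regression import (
    GrufRegressor,
    pls_regress,
    svd_embed,
    symmetric_embed,
)


def nipals_pls2(x, y, n_components):
    """Brute-force uncentered NIPALS oracle (iterative inner loop)."""
    xk, yk = x.copy(), y.copy()
    W, P, C = [], [], []
    for _ in range(n_components):
        u = yk[:, int(np.argmax(np.linalg.norm(yk, axis=0)))]
        if np.linalg.norm(u) < 1e-14:
            break
        for _ in range(500):
            w = xk.T @ u
            w /= np.linalg.norm(w)
            t = xk @ w
            c = yk.T @ t / (t @ t)
            u_new = yk @ c / (c @ c)
            if np.linalg.norm(u_new - u) < 1e-13 * (1 + np.linalg.norm(u)):
                u = u_new
                break
            u = u_new
        t = xk @ w
        tt = t @ t
        p = xk.T @ t / tt
        c = yk.T @ t / tt
        xk = xk - np.outer(t, p)
        yk = yk - np.outer(t, c)
        W.append(w), P.append(p), C.append(c)
    W, P, C = (np.column_stack(m) for m in (W, P, C))
    return W @ np.linalg.solve(P.T @ W, C.T)


class TestSvdEmbed:
    def test_identity_reconstruction(self):
        l, r = svd_embed(np.eye(2), 2)
        np.testing.assert_allclose(l.factors @ r.factors.T, np.eye(2), atol=1e-10)

    def test_diagonal_closed_form(self):
        l, r = svd_embed(np.array([[4.0, 0.0], [0.0, 0.0]]), 1)
        np.testing.assert_allclose(l.factors @ r.factors.T,
                                   [[4.0, 0.0], [0.0, 0.0]], atol=1e-12)
        np.testing.assert_allclose(np.abs(l.factors), [[2.0], [0.0]], atol=1e-12)

    def test_truncation_error_matches_discarded_spectrum(self, rng):
        m = rng.normal(size=(6, 5))
        sigma = np.linalg.svd(m, compute_uv=False)  # independent full-SVD oracle
        l, r = svd_embed(m, 3)
        err = np.linalg.norm(m - l.factors @ r.factors.T)
        np.testing.assert_allclose(err, np.sqrt((sigma[3:] ** 2).sum()), atol=1e-9)

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError, match="rank"):
            svd_embed(np.eye(3), 4)

    def test_sign_convention_is_deterministic(self, rng):
        m = rng.normal(size=(5, 4))
        l1, _ = svd_embed(m, 2)
        l2, _ = svd_embed(m.copy(), 2)
        np.testing.assert_array_equal(l1.factors, l2.factors)
        for j in range(2):
            col = l1.factors[:, j]
            assert col[np.argmax(np.abs(col))] >= 0


class TestSymmetricEmbed:
    def test_identity(self):
        f = symmetric_embed(np.eye(3), 3)
        np.testing.assert_allclose(f.factors @ f.factors.T, np.eye(3), atol=1e-10)

    def test_all_ones_rank_one(self):
        f = symmetric_embed(np.ones((2, 2)), 1)
        np.testing.assert_allclose(np.abs(f.factors), [[1.0], [1.0]], atol=1e-12)
        np.testing.assert_allclose(f.factors @ f.factors.T, np.ones((2, 2)), atol=1e-12)

    def test_psd_gram_full_reconstruction(self, rng):
        g = rng.normal(size=(8, 8))
        s = g @ g.T
        f = symmetric_embed(s, 8)
        assert np.linalg.norm(s - f.factors @ f.factors.T) < 1e-8

    def test_negative_eigenvalues_clipped(self):
        s = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        f = symmetric_embed(s)  # indefinite; factors must stay real
        assert np.isrealobj(f.factors)
        assert (f.singular_values >= 0).all()

    def test_asymmetric_input_rejected(self, rng):
        s = rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            symmetric_embed(s, 2)


class TestPls:
    def test_zero_response_gives_zero_coefficients(self, rng):
        x = rng.normal(size=(6, 3))
        np.testing.assert_array_equal(pls_regress(x, np.zeros((6, 2)), 2),
                                      np.zeros((3, 2)))

    def test_exact_linear_recovery_at_full_rank(self, rng):
        x = rng.normal(size=(8, 3))
        b_true = rng.normal(size=(3, 2))
        b = pls_regress(x, x @ b_true, 3)
        assert np.linalg.norm(x @ b - x @ b_true) < 1e-8

    def test_single_component_matches_nipals_oracle(self, rng):
        x = rng.normal(size=(10, 4)) @ np.diag([3.0, 1.0, 0.5, 0.2])
        y = rng.normal(size=(10, 2))
        b = pls_regress(x, y, 1)
        oracle = nipals_pls2(x, y, 1)
        np.testing.assert_allclose(x @ b, x @ oracle, atol=1e-8)

    def test_multi_component_matches_nipals_oracle(self, rng):
        x = rng.normal(size=(12, 5))
        y = rng.normal(size=(12, 3))
        np.testing.assert_allclose(
            x @ pls_regress(x, y, 3), x @ nipals_pls2(x, y, 3), atol=1e-7
        )

    def test_matches_sklearn_on_centered_data(self, rng):
        # sklearn always centers; on pre-centered data the fits coincide
        from sklearn.cross_decomposition import PLSRegression

        x = rng.normal(size=(20, 4))
        y = rng.normal(size=(20, 2))
        x -= x.mean(axis=0)
        y -= y.mean(axis=0)
        ours = x @ pls_regress(x, y, 4)
        theirs = PLSRegression(n_components=4, scale=False).fit(x, y).predict(x)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_all_zero_predictors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pls_regress(np.zeros((4, 2)), np.ones((4, 1)), 1)


def planted_bilinear(rng, m=12, n=10, p=4, q=3):
    """A = F_r Theta F_d' built from planted PSD similarity factors."""
    fr = rng.normal(size=(m, p))
    fd = rng.normal(size=(n, q))
    s_r = fr @ fr.T
    s_d = fd @ fd.T
    theta = rng.normal(size=(p, q))
    a = fr @ theta @ fd.T
    return a, s_r, s_d


class TestGrufRegressor:
    def test_theta_is_product_of_coefficients(self, rng):
        a, s_r, s_d = planted_bilinear(rng)
        model = GrufRegressor().fit(np.abs(a), _sim(s_r), _sim(s_d))
        np.testing.assert_allclose(model.theta_, model.br_ @ model.bd_.T, atol=1e-12)

    def test_planted_self_consistency(self, rng):
        a, s_r, s_d = planted_bilinear(rng)
        # full-rank regressions (components = rank of each latent basis)
        model = GrufRegressor(n_components=16).fit(
            a, s_r / _scale(s_r), s_d / _scale(s_d)
        )
        # scaling S only rescales factors; the bilinear span is unchanged
        scores = model.predict("T1").scores
        np.testing.assert_allclose(scores, a, atol=1e-6)

    def test_zero_association_gives_zero_theta(self, rng):
        _, s_r, s_d = planted_bilinear(rng)
        model = GrufRegressor().fit(np.zeros((12, 10)), s_r, s_d)
        np.testing.assert_array_equal(model.theta_, 0.0)
        np.testing.assert_array_equal(model.predict("T1").scores, 0.0)

    def test_lncrna_permutation_permutes_prediction_rows(self, planted):
        a = planted.lda_binary
        model = GrufRegressor(rank_assoc=5, rank_lncrna=5, rank_disease=5)
        ref = model.fit(a, planted.S_r, planted.S_d).predict("T1").scores
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(a.lncrna_ids))
        from gruf.containers import LdaMatrix

        a_p = LdaMatrix(tuple(a.lncrna_ids[i] for i in perm), a.disease_ids,
                        a.values[perm], "binary")
        s_r_p = SimilarityMatrix(
            tuple(a.lncrna_ids[i] for i in perm),
            planted.S_r.values[np.ix_(perm, perm)],
        )
        got = model.fit(a_p, s_r_p, planted.S_d).predict("T1").scores
        np.testing.assert_allclose(got, ref[perm], atol=1e-8)

    def test_id_mismatch_reports_offenders(self, planted):
        a = planted.lda_binary
        wrong = SimilarityMatrix(
            tuple(f"x{i}" for i in range(len(a.lncrna_ids))), planted.S_r.values
        )
        with pytest.raises(ValueError, match="positions"):
            GrufRegressor().fit(a, wrong, planted.S_d)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            GrufRegressor().predict("T1")


class TestColdStartProjection:
    def test_training_row_projects_onto_its_latent_row(self, rng):
        g = rng.normal(size=(9, 9))
        s = g @ g.T  # full-rank PSD
        f = symmetric_embed(s, 9)
        for i in (0, 4, 8):
            np.testing.assert_allclose(
                f.project(s[i]), f.factors[i][None, :], atol=1e-8
            )

    def test_zero_similarity_projects_to_zero(self, rng):
        f = symmetric_embed(np.eye(5), 5)
        np.testing.assert_array_equal(f.project(np.zeros(5)), np.zeros((1, 5)))

    def test_t2_on_training_row_equals_t1_row(self, rng):
        a, s_r, s_d = planted_bilinear(rng, m=10, n=8, p=10, q=8)
        model = GrufRegressor().fit(a, _sim(s_r), _sim(s_d))
        t1 = model.predict("T1").scores
        t2 = model.predict("T2", s_new_lncrna=_sim(s_r)[[3]]).scores
        np.testing.assert_allclose(t2[0], t1[3], atol=1e-6)

    def test_t2_t3_swap_under_transposition(self, rng):
        a, s_r, s_d = planted_bilinear(rng)
        m1 = GrufRegressor().fit(a, _sim(s_r), _sim(s_d))
        m2 = GrufRegressor().fit(a.T, _sim(s_d), _sim(s_r))
        rows = _sim(s_r)[[2]]
        t2 = m1.predict("T2", s_new_lncrna=rows).scores
        t3 = m2.predict("T3", s_new_disease=rows).scores
        np.testing.assert_allclose(t2, t3.T, atol=1e-6)

    def test_t4_single_pair_is_scalar(self, rng):
        a, s_r, s_d = planted_bilinear(rng)
        model = GrufRegressor().fit(a, _sim(s_r), _sim(s_d))
        out = model.predict(
            "T4", s_new_lncrna=_sim(s_r)[[0]], s_new_disease=_sim(s_d)[[1]]
        )
        assert out.scores.shape == (1, 1)

    def test_length_mismatch_errors(self, rng):
        f = symmetric_embed(np.eye(5), 5)
        with pytest.raises(ValueError, match="do not match"):
            f.project(np.zeros(4))


def _scale(s):
    return np.abs(s).max()


def _sim(s):
    """Rescale an arbitrary PSD Gram matrix into a unit-diagonal similarity-like
    symmetric matrix domain is irrelevant for the algebraic tests."""
    return s / _scale(s)
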