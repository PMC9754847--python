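import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preictal import (
    DynamicConnectivity,
    Epoch,
    EpochSet,
    KernelSpec,
    build_predictor_matrix,
    averaged_covariance,
    epoch_to_network_vector,
    graphical_lasso,
    kernel_weights,
    partial_correlation,
    vectorize_upper,
    edge_names_for,
)
from preictal.connectivity import kkt_residual, weighted_covariance


def brute_weighted_cov(X, t, h, center=True):
    """Literal double-loop evaluation of the kernel-weighted covariance."""
    X = np.asarray(X, float)
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    p, q = X.shape
    num = np.zeros((p, p))
    den = 0.0
    for i in range(1, q + 1):
        w = np.exp(-0.5 * ((abs(i - t)) / h) ** 2)
        x = X[:, i - 1]
        num += w * np.outer(x, x)
        den += w
    return num / den


def glasso_objective(S, omega, lam):
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return np.inf
    return np.tensordot(S, omega) - logdet + lam * (
        np.abs(omega).sum() - np.abs(np.diag(omega)).sum())


def random_spd(rng, p, cond=5.0):
    A = rng.standard_normal((p, p))
    S = A @ A.T + cond * np.eye(p)
    return 0.5 * (S + S.T)


class TestKernelWeights:
    def test_self_weight_is_one(self):
        for t in (1, 17, 60):
            w = kernel_weights(t, 60)
            assert w[t - 1] == 1.0
            assert np.all((w > 0) & (w <= 1))

    def test_power_third_bandwidth(self):
        spec = KernelSpec(bandwidth_rule="power_third")
        assert spec.bandwidth_for(60) == pytest.approx(60 ** (1 / 3))

    @given(t=st.integers(1, 60), k=st.integers(1, 30))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_around_t(self, t, k):
        """w_{t-k} = w_{t+k} whenever both indices are valid."""
        q = 60
        if t - k < 1 or t + k > q:
            return
        w = kernel_weights(t, q)
        assert w[t - k - 1] == pytest.approx(w[t + k - 1])


class TestWeightedCovariance:
    def test_matches_double_loop_oracle(self, rng):
        X = rng.standard_normal((3, 60))
        spec = KernelSpec()
        h = spec.bandwidth_for(60)
        got = weighted_covariance(X, 30, spec).matrix
        want = brute_weighted_cov(X, 30, h)
        assert np.abs(got - want).max() < 1e-12

    def test_uniform_weight_limit_is_sample_covariance(self, rng):
        """h -> infinity makes all weights equal: the ordinary covariance
        with divisor q."""
        X = rng.standard_normal((4, 50))
        spec = KernelSpec(bandwidth_rule="fixed", bandwidth=1e9)
        Xc = X - X.mean(axis=1, keepdims=True)
        plain = Xc @ Xc.T / 50
        assert np.abs(weighted_covariance(X, 25, spec).matrix - plain).max() < 1e-9
        assert np.abs(averaged_covariance(X, spec).matrix - plain).max() < 1e-9

    def test_scalar_variance_case(self):
        """p=1, centered data (a, -a): the weighted variance is a^2 for any
        t because both observations carry the same squared value."""
        a = 1.7
        X = np.array([[a, -a]])
        got = weighted_covariance(X, 1, KernelSpec(bandwidth_rule="fixed", bandwidth=2.0),
                                  center=True).matrix
        assert got[0, 0] == pytest.approx(a * a)

    def test_averaged_matches_brute_average(self, rng):
        X = rng.standard_normal((4, 60))
        spec = KernelSpec()
        h = spec.bandwidth_for(60)
        want = np.mean([brute_weighted_cov(X, t, h) for t in range(1, 61)], axis=0)
        got = averaged_covariance(X, spec).matrix
        assert np.abs(got - want).max() < 1e-12

    def test_psd(self, rng):
        X = rng.standard_normal((5, 40))
        S = averaged_covariance(X).matrix
        assert np.linalg.eigvalsh(S).min() > -1e-10


class TestGraphicalLasso:
    def test_zero_penalty_recovers_inverse(self, rng):
        S = random_spd(rng, 6)
        est = graphical_lasso(S, 0.0)
        assert np.abs(est.matrix - np.linalg.inv(S)).max() < 1e-6

    def test_identity_input_identity_output(self):
        for lam in (0.05, 0.3, 1.0):
            est = graphical_lasso(np.eye(4), lam, tol=1e-9)
            assert np.abs(est.matrix - np.eye(4)).max() < 1e-8
            assert est.support == set()

    @pytest.mark.parametrize("s,lam", [(0.1, 0.2), (0.3, 0.3), (0.6, 0.2), (0.9, 0.05)])
    def test_two_by_two_closed_form(self, s, lam):
        """For S = [[1, s], [s, 1]]: |s| <= lam gives a diagonal solution
        with unit diagonal; |s| > lam matches the closed form built from
        the soft-thresholded covariance s* = sign(s)(|s| - lam)."""
        S = np.array([[1.0, s], [s, 1.0]])
        est = graphical_lasso(S, lam, tol=1e-9)
        if abs(s) <= lam:
            want = np.eye(2)
        else:
            s_star = np.sign(s) * (abs(s) - lam)
            want = np.linalg.inv(np.array([[1.0, s_star], [s_star, 1.0]]))
        assert np.abs(est.matrix - want).max() < 1e-6

    def test_two_by_two_beats_dense_grid(self, rng):
        """Solver objective is no worse than a dense grid search over 2x2
        SPD matrices (independent oracle)."""
        S = random_spd(rng, 2, cond=1.0)
        sd = np.sqrt(np.diag(S))
        S = S / np.outer(sd, sd)
        lam = 0.15
        est = graphical_lasso(S, lam, tol=1e-8)
        d = np.linspace(0.2, 5.0, 80)
        o = np.linspace(-3.0, 3.0, 121)
        D1, D2, O = np.meshgrid(d, d, o, indexing="ij")
        det = D1 * D2 - O**2
        valid = det > 1e-12
        obj = S[0, 0] * D1 + S[1, 1] * D2 + 2 * S[0, 1] * O \
            - np.where(valid, np.log(np.where(valid, det, 1.0)), -np.inf) \
            + lam * 2 * np.abs(O)
        obj[~valid] = np.inf
        assert glasso_objective(S, est.matrix, lam) <= obj.min() + 1e-4

    def test_objective_monotone(self, rng):
        S = random_spd(rng, 8, cond=1.0)
        sd = np.sqrt(np.diag(S))
        est = graphical_lasso(S / np.outer(sd, sd), 0.1)
        assert np.all(np.diff(est.objective_path) <= 1e-12)

    def test_kkt_at_convergence(self, rng):
        S = random_spd(rng, 7, cond=0.5)
        lam = 0.2
        est = graphical_lasso(S, lam, tol=1e-6)
        assert kkt_residual(S, est.matrix, lam) <= 1e-6

    @pytest.mark.filterwarnings("ignore::UserWarning", "ignore:graphical_lasso")
    def test_matches_sklearn(self, rng):
        """Independent cross-check against sklearn's graphical lasso."""
        from sklearn.covariance import graphical_lasso as sk_glasso

        S = random_spd(rng, 5, cond=1.0)
        sd = np.sqrt(np.diag(S))
        S = S / np.outer(sd, sd)
        lam = 0.1
        est = graphical_lasso(S, lam, tol=1e-9)
        _, prec = sk_glasso(S, alpha=lam, tol=1e-10, max_iter=2000)
        assert glasso_objective(S, est.matrix, lam) <= glasso_objective(S, prec, lam) + 1e-6
        assert np.abs(est.matrix - prec).max() < 1e-3

    def test_sparsity_monotone_in_lambda(self, rng):
        S = random_spd(rng, 10, cond=0.5)
        sd = np.sqrt(np.diag(S))
        S = S / np.outer(sd, sd)
        sizes = [len(graphical_lasso(S, lam).support)
                 for lam in (0.01, 0.05, 0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_asymmetric_input_rejected(self):
        S = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            graphical_lasso(S, 0.1)

    def test_zero_variance_channel_floored(self, rng):
        S = random_spd(rng, 4)
        S[2, :] = 0.0
        S[:, 2] = 0.0
        est = graphical_lasso(S, 0.1)
        assert np.all(np.isfinite(est.matrix))


class TestSelectLambdaBic:
    def test_returns_grid_member_and_prefers_sparsity_on_noise(self, rng):
        """On independent-channel epochs the BIC selector picks a penalty
        from the grid that yields a sparse pooled precision."""
        from preictal import select_lambda_bic

        epochs = [rng.standard_normal((5, 60)) for _ in range(10)]
        grid = (0.02, 0.1, 0.4)
        lam = select_lambda_bic(epochs, grid=grid)
        assert lam in grid
        # independence truth: the selected penalty should not be the
        # weakest one, which keeps many spurious edges
        assert lam > grid[0]

    def test_deterministic(self, rng):
        from preictal import select_lambda_bic

        epochs = [rng.standard_normal((4, 60)) for _ in range(6)]
        assert select_lambda_bic(epochs) == select_lambda_bic(epochs)


class TestPartialCorrelation:
    def test_identity(self):
        assert np.array_equal(partial_correlation(np.eye(3)), np.eye(3))

    def test_two_by_two_value(self):
        W = partial_correlation(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert W[0, 1] == pytest.approx(0.5)
        assert W[0, 0] == 1.0

    def test_bounded_and_sign_flipped(self, rng):
        """For SPD precision input: |W_ij| <= 1 and sign(W_ij) =
        -sign(omega_ij); the zero patterns coincide."""
        for _ in range(10):
            omega = random_spd(rng, 6, cond=3.0)
            mask = rng.random((6, 6)) < 0.5
            mask = np.triu(mask, 1)
            omega[mask | mask.T] = 0.0
            omega = omega + (abs(min(np.linalg.eigvalsh(omega).min(), 0)) + 0.1) * np.eye(6)
            W = partial_correlation(omega)
            off = ~np.eye(6, dtype=bool)
            assert np.all(np.abs(W[off]) <= 1 + 1e-12)
            nz = off & (omega != 0)
            assert np.all(np.sign(W[nz]) == -np.sign(omega[nz]))
            assert np.all(W[off & (omega == 0)] == 0)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            partial_correlation(np.array([[0.0, 0.1], [0.1, 1.0]]))


class TestVectorizeUpper:
    @pytest.mark.parametrize("p,d", [(21, 210), (19, 171), (2, 1)])
    def test_length(self, p, d):
        W = np.eye(p)
        assert vectorize_upper(W).size == d

    def test_row_order(self):
        W = np.array([[1, 12, 13], [12, 1, 23], [13, 23, 1]], dtype=float)
        assert np.array_equal(vectorize_upper(W), [12, 13, 23])

    def test_round_trip(self, rng):
        p = 5
        W = random_spd(rng, p)
        W = 0.5 * (W + W.T)
        v = vectorize_upper(W)
        back = np.diag(np.diag(W)).astype(float)
        iu, ju = np.triu_indices(p, 1)
        back[iu, ju] = v
        back[ju, iu] = v
        assert np.array_equal(back, W)

    def test_edge_names_aligned(self):
        names = edge_names_for(["A", "B", "C"])
        assert names == ["A--B", "A--C", "B--C"]


class TestEpochToNetworkVector:
    def test_deterministic(self, rng):
        X = rng.standard_normal((4, 60))
        v1 = epoch_to_network_vector(X, lam=0.1)
        v2 = epoch_to_network_vector(X.copy(), lam=0.1)
        assert np.array_equal(v1, v2)

    def test_strong_penalty_kills_edges(self, rng):
        X = rng.standard_normal((5, 60))
        v = epoch_to_network_vector(X, lam=2.0)
        assert np.abs(v).max() < 1e-10

    def test_correlated_pair_dominates(self, rng):
        """Two near-identical channels produce the largest-magnitude edge."""
        X = rng.standard_normal((4, 60))
        X[1] = X[0] + 0.05 * rng.standard_normal(60)
        v = epoch_to_network_vector(X, lam=0.05)
        assert np.argmax(np.abs(v)) == 0  # edge (0,1) is index 0

    def test_permutation_equivariance(self, rng):
        """Permuting channels permutes the recovered edges consistently."""
        p = 5
        X = rng.standard_normal((p, 80))
        X[2] = X[0] + 0.1 * rng.standard_normal(80)
        perm = np.array([3, 0, 4, 1, 2])
        v = epoch_to_network_vector(X, lam=0.05)
        v_perm = epoch_to_network_vector(X[perm], lam=0.05)

        def as_matrix(vec):
            M = np.zeros((p, p))
            iu, ju = np.triu_indices(p, 1)
            M[iu, ju] = vec
            return M + M.T

        W, Wp = as_matrix(v), as_matrix(v_perm)
        assert np.allclose(Wp, W[np.ix_(perm, perm)], atol=1e-6)


class TestPredictorMatrix:
    def test_network_mode_shape_and_order(self, rng):
        epochs = [Epoch(data=rng.standard_normal((19, 60)), label=int(i < 3),
                        epoch_index=i) for i in range(8)]
        pm = build_predictor_matrix(EpochSet(epochs=epochs), mode="network")
        assert pm.V.shape == (8, 171)
        assert np.array_equal(pm.Z, [1, 1, 1, 0, 0, 0, 0, 0])
        assert len(pm.edge_names) == 171

    @pytest.mark.parametrize("mode,cols", [("raw", 4 * 60), ("combined", 6 + 240)])
    def test_raw_and_combined_columns(self, tiny_epoch_set, mode, cols):
        pm = build_predictor_matrix(tiny_epoch_set, mode=mode, lam=0.2)
        assert pm.V.shape == (len(tiny_epoch_set), cols)

    def test_raw_mode_is_row_major_flatten(self, tiny_epoch_set):
        pm = build_predictor_matrix(tiny_epoch_set, mode="raw")
        first_pre = [e for e in tiny_epoch_set.epochs if e.label == 1][0]
        assert np.array_equal(pm.V[0], first_pre.data.ravel())

    def test_mixed_shapes_rejected(self, rng):
        epochs = [Epoch(data=rng.standard_normal((3, 60)), label=1),
                  Epoch(data=rng.standard_normal((4, 60)), label=0)]
        with pytest.raises(ValueError, match="mixed"):
            EpochSet(epochs=epochs)


class TestDynamicConnectivityEstimator:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        tf = DynamicConnectivity(lam=0.3, feature_mode="raw")
        tf2 = clone(tf)
        assert tf2.get_params()["lam"] == 0.3
        tf2.set_params(lam=0.1)
        assert tf2.lam == 0.1

    def test_pipeline_composition(self, planted_epochs):
        """The transformer chains with the ensemble classifier inside a
        sklearn Pipeline."""
        from sklearn.pipeline import Pipeline

        from preictal import BootstrapLassoLogistic

        eset, _ = planted_epochs
        sub = EpochSet(epochs=eset.epochs[:20] + eset.epochs[-20:])
        data = np.stack([e.data for e in sub.epochs])
        y = np.array([e.label for e in sub.epochs])
        pipe = Pipeline([
            ("connectivity", DynamicConnectivity(lam=0.1)),
            ("classifier", BootstrapLassoLogistic(B=5, lambda_rule="fixed",
                                                  C=0.5, random_state=0)),
        ])
        pipe.fit(data, y)
        proba = pipe.predict_proba(data)
        assert proba.shape == (40, 2)
        assert np.all((proba >= 0) & (proba <= 1))
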