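"""Per-epoch dynamic functional connectivity via time-varying graphical lasso.

Each epoch X (p electrodes x q seconds) is modeled as matrix-normal with a
separable covariance Sigma_T (x) Sigma_S. The spatial precision matrix
Omega = Sigma_S^{-1} is estimated sparsely: a Gaussian-kernel-weighted
covariance is formed at every time point t,

    S_hat(t) = sum_i w_it x_i x_i' / sum_i w_it,   w_it = K(|i - t| / h),

the q estimates are averaged, and the graphical lasso

    min_Omega  Tr(S Omega) - log det Omega + lambda * ||Omega||_1,off

is solved on the average. Edge strengths are the partial correlations
-omega_ij / sqrt(omega_ii * omega_jj); the upper triangle, read by row,
becomes one row of the network predictor matrix V (n x p(p-1)/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .epoching import Epoch, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "CovarianceEstimate",
    "PrecisionEstimate",
    "NetworkPredictorMatrix",
    "kernel_weights",
    "weighted_covariance",
    "averaged_covariance",
    "graphical_lasso",
    "select_lambda_bic",
    "partial_correlation",
    "vectorize_upper",
    "edge_names_for",
    "epoch_to_network_vector",
    "build_predictor_matrix",
    "DynamicConnectivity",
]

SUPPORT_TOL = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian smoothing kernel for the time-varying covariance.

    ``bandwidth_rule="power_third"`` sets h = q**(1/3) from the epoch length
    q at evaluation time (the kernel smooths over within-epoch time points);
    ``"fixed"`` uses the ``bandwidth`` field as-is.
    """

    kernel: str = "gaussian"
    bandwidth: float = 1.0
    bandwidth_rule: str = "power_third"

    def __post_init__(self) -> None:
        if self.kernel != "gaussian":
            raise ValueError("only the gaussian kernel is supported")
        if self.bandwidth_rule not in ("power_third", "fixed"):
            raise ValueError("bandwidth_rule must be 'power_third' or 'fixed'")
        if self.bandwidth_rule == "fixed" and not self.bandwidth > 0:
            raise ValueError("fixed bandwidth must be positive")

    def bandwidth_for(self, q: int) -> float:
        if self.bandwidth_rule == "power_third":
            return float(q) ** (1.0 / 3.0)
        return float(self.bandwidth)


@dataclass
class CovarianceEstimate:
    """A p x p symmetric PSD covariance at one time index or averaged."""

    matrix: np.ndarray
    time_index: int | str = "averaged"


@dataclass
class PrecisionEstimate:
    """Sparse symmetric positive-definite precision matrix with its penalty."""

    matrix: np.ndarray
    penalty: float
    support: set[tuple[int, int]] = field(default_factory=set)
    n_iter: int = 0
    objective_path: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.support:
            self.support = _support_of(self.matrix)


def _support_of(omega: np.ndarray, tol: float = SUPPORT_TOL) -> set[tuple[int, int]]:
    p = omega.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    keep = np.abs(omega[iu, ju]) > tol
    return {(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])}


@dataclass
class NetworkPredictorMatrix:
    """Stacked per-epoch feature rows with labels and edge names.

    Rows are ordered preictal block (n1 rows) then interictal block (n2
    rows). In ``network`` mode columns are the d = p(p-1)/2 vectorized
    edges; ``raw`` flattens each epoch row-major to length p*q; ``combined``
    concatenates [network | raw].
    """

    V: np.ndarray
    Z: np.ndarray
    edge_names: list[str]
    feature_mode: str = "network"

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.Z = np.asarray(self.Z, dtype=int)
        if self.V.shape[0] != self.Z.shape[0]:
            raise ValueError("V and Z row counts differ")


def kernel_weights(t: int, q: int, spec: KernelSpec = KernelSpec()) -> np.ndarray:
    """Gaussian kernel weights w_i = exp(-((|i-t|)/h)^2 / 2) for i = 1..q.

    ``t`` is 1-based to match the time-point indexing of the epoch columns.
    """
    if not 1 <= t <= q:
        raise ValueError(f"time index t={t} outside 1..{q}")
    h = spec.bandwidth_for(q)
    i = np.arange(1, q + 1, dtype=float)
    u = np.abs(i - t) / h
    return np.exp(-0.5 * u * u)


def _prepare(X: np.ndarray, center: bool) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch matrix must be 2-D (electrodes x time)")
    if X.shape[1] < 2:
        raise ValueError("need at least q = 2 time points")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    return X


def weighted_covariance(
    X: np.ndarray, t: int, spec: KernelSpec = KernelSpec(), center: bool = True
) -> CovarianceEstimate:
    """Kernel-weighted covariance at time index ``t`` (1-based).

    S_hat(t) = sum_i w_it x_i x_i' / sum_i w_it with x_i the i-th column of
    the (optionally per-electrode mean-centered) epoch.
    """
    X = _prepare(X, center)
    w = kernel_weights(t, X.shape[1], spec)
    S = (X * w) @ X.T / w.sum()
    return CovarianceEstimate(matrix=0.5 * (S + S.T), time_index=t)


def averaged_covariance(
    X: np.ndarray, spec: KernelSpec = KernelSpec(), center: bool = True
) -> CovarianceEstimate:
    """Average of the q kernel-weighted covariances over t = 1..q.

    Because every S_hat(t) is X diag(w_t / sum w_t) X', the average equals
    X diag(d) X' with d the mean of the normalized weight vectors — computed
    that way for speed, identical to the literal average.
    """
    X = _prepare(X, center)
    q = X.shape[1]
    W = np.stack([kernel_weights(t, q, spec) for t in range(1, q + 1)])
    d = (W / W.sum(axis=1, keepdims=True)).mean(axis=0)
    S = (X * d) @ X.T
    return CovarianceEstimate(matrix=0.5 * (S + S.T), time_index="averaged")


def _objective(S: np.ndarray, omega: np.ndarray, lam: float,
               penalize_diagonal: bool) -> float:
    # PD check must go through Cholesky: det > 0 alone also accepts
    # indefinite matrices with an even number of negative eigenvalues,
    # where the log-det objective is unbounded below
    try:
        L = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    pen = np.abs(omega).sum()
    if not penalize_diagonal:
        pen -= np.abs(np.diag(omega)).sum()
    return float(np.tensordot(S, omega) - logdet + lam * pen)


def _soft_threshold(A: np.ndarray, thr: float, penalize_diagonal: bool) -> np.ndarray:
    out = np.sign(A) * np.maximum(np.abs(A) - thr, 0.0)
    if not penalize_diagonal:
        np.fill_diagonal(out, np.diag(A))
    return out


def kkt_residual(S: np.ndarray, omega: np.ndarray, lam: float,
                 penalize_diagonal: bool = False, tol: float = SUPPORT_TOL) -> float:
    """Max stationarity violation of the graphical-lasso optimality system.

    G = S - Omega^{-1}. On penalized nonzero entries |G + lam*sign(omega)|
    must vanish; on penalized zeros |G| <= lam; on unpenalized entries |G|
    must vanish.
    """
    G = S - np.linalg.inv(omega)
    p = S.shape[0]
    penal = np.ones((p, p), dtype=bool)
    if not penalize_diagonal:
        np.fill_diagonal(penal, False)
    active = np.abs(omega) > tol
    res = 0.0
    r_active = np.abs(G + lam * np.sign(omega))[penal & active]
    if r_active.size:
        res = max(res, r_active.max())
    r_zero = np.maximum(np.abs(G) - lam, 0.0)[penal & ~active]
    if r_zero.size:
        res = max(res, r_zero.max())
    r_free = np.abs(G)[~penal]
    if r_free.size:
        res = max(res, r_free.max())
    return float(res)


def _newton_refine(S: np.ndarray, omega: np.ndarray, lam: float,
                   penalize_diagonal: bool, obj: float,
                   max_newton: int = 20) -> tuple[np.ndarray, list[float]]:
    """Orthant-restricted Newton polish on the current support.

    With the active set and the signs of its entries frozen, the objective
    is smooth in the free entries (diagonal + active off-diagonal pairs);
    Newton steps with a PD/orthant/monotonicity line search converge
    quadratically. Entries attempting to cross zero simply shorten the
    step, leaving the outer proximal loop to change the support.
    """
    p = S.shape[0]
    act = np.abs(omega) > SUPPORT_TOL
    iu, ju = np.triu_indices(p, k=1)
    keep = act[iu, ju]
    oi, oj = iu[keep], ju[keep]
    signs = np.sign(omega[oi, oj])
    n_diag, n_off = p, oi.size
    path: list[float] = []

    for _ in range(max_newton):
        sigma = np.linalg.inv(omega)
        g = np.empty(n_diag + n_off)
        g[:n_diag] = np.diag(S) - np.diag(sigma)
        if penalize_diagonal:
            g[:n_diag] += lam  # diagonal of a PD matrix is positive
        g[n_diag:] = 2.0 * (S[oi, oj] - sigma[oi, oj] + lam * signs)

        # Hessian of -logdet in the paired parametrization
        H = np.empty((n_diag + n_off, n_diag + n_off))
        H[:n_diag, :n_diag] = sigma ** 2
        if n_off:
            H[:n_diag, n_diag:] = 2.0 * sigma[:, oi] * sigma[:, oj]
            H[n_diag:, :n_diag] = H[:n_diag, n_diag:].T
            H[n_diag:, n_diag:] = 2.0 * (
                sigma[np.ix_(oi, oi)] * sigma[np.ix_(oj, oj)]
                + sigma[np.ix_(oi, oj)] * sigma[np.ix_(oj, oi)]
            )
        try:
            d = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), -g)
        except np.linalg.LinAlgError:
            break

        accepted = False
        t = 1.0
        for _ in range(30):
            cand = omega.copy()
            cand[np.diag_indices(p)] += t * d[:n_diag]
            if n_off:
                new = cand[oi, oj] + t * d[n_diag:]
                # orthant projection: entries crossing zero are clipped to it
                new[np.sign(new) != signs] = 0.0
                cand[oi, oj] = new
                cand[oj, oi] = new
            cand_obj = _objective(S, cand, lam, penalize_diagonal)
            if cand_obj <= obj + 1e-15:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        omega, obj = cand, cand_obj
        path.append(obj)
        if np.abs(g).max() < 1e-12:
            break
    return omega, path


def graphical_lasso(
    S: np.ndarray,
    lam: float,
    penalize_diagonal: bool = False,
    ridge_eps: float = 1e-8,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> PrecisionEstimate:
    """Sparse precision estimation by L1-penalized Gaussian likelihood.

    Minimizes Tr(S*Omega) - log det(Omega) + lam * ||Omega||_1 (off-diagonal
    penalty by default). The solver alternates monotone accelerated
    proximal-gradient sweeps (MFISTA with backtracking, which identify the
    support) with orthant-restricted Newton refinements on the active set
    (which polish it to high accuracy); no accepted iterate can increase the
    objective, and convergence is declared when the KKT stationarity
    residual drops below ``tol``. ``lam = 0`` is solved in closed form as
    the (ridged when necessary) inverse of S.

    Zero-variance channels have their variance floored at ``ridge_eps``.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    S = 0.5 * (S + S.T)
    p = S.shape[0]

    dead = np.diag(S) < ridge_eps
    if dead.any():
        logger.warning("flooring %d zero-variance channel(s) at ridge_eps", dead.sum())
        S = S.copy()
        S[np.diag_indices(p)] = np.maximum(np.diag(S), ridge_eps)

    if lam == 0.0:
        evals = np.linalg.eigvalsh(S)
        if evals.min() < ridge_eps:
            S = S + ridge_eps * np.eye(p)
        omega = np.linalg.inv(S)
        omega = 0.5 * (omega + omega.T)
        return PrecisionEstimate(matrix=omega, penalty=0.0, n_iter=0,
                                 objective_path=[_objective(S, omega, 0.0, penalize_diagonal)])

    # PD warm start: inverse of a diagonally-loaded S
    evals = np.linalg.eigvalsh(S)
    load = max(0.0, -evals.min()) + max(lam, 1e-3)
    omega = np.linalg.inv(S + load * np.eye(p))
    omega = 0.5 * (omega + omega.T)

    obj = _objective(S, omega, lam, penalize_diagonal)
    path = [obj]
    y = omega.copy()
    t_k = 1.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ev_y = np.linalg.eigvalsh(y)
        f_y = _objective(S, y, 0.0, penalize_diagonal) if ev_y[0] > 0 else np.inf
        # adaptive restart: extrapolation left the PD cone or overshot
        if ev_y[0] <= 0 or f_y > _objective(S, omega, 0.0, penalize_diagonal) + 1.0:
            y = omega.copy()
            ev_y = np.linalg.eigvalsh(y)
            f_y = _objective(S, y, 0.0, penalize_diagonal)
            t_k = 1.0
        grad = S - np.linalg.inv(y)
        # natural step for the log-det gradient: inverse local Lipschitz
        # constant 1/||y^{-1}||^2 = lambda_min(y)^2 (capped for safety)
        step = 0.95 * min(float(ev_y[0]) ** 2, 1e6)
        z = y
        for _ in range(60):
            z = _soft_threshold(y - step * grad, step * lam, penalize_diagonal)
            z = 0.5 * (z + z.T)
            f_z = _objective(S, z, 0.0, penalize_diagonal)
            d = z - y
            # standard FISTA backtracking: smooth part majorized at y
            if f_z <= f_y + np.tensordot(grad, d) + (d * d).sum() / (2 * step) + 1e-12:
                break
            step *= 0.5
        z_obj = _objective(S, z, lam, penalize_diagonal)
        # monotone variant: keep the better of {z, previous omega}
        omega_new, obj_new = (z, z_obj) if z_obj <= obj else (omega, obj)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        y = omega_new + (t_k / t_next) * (z - omega_new) \
            + ((t_k - 1.0) / t_next) * (omega_new - omega)
        omega, obj, t_k = omega_new, obj_new, t_next
        path.append(obj)
        if kkt_residual(S, omega, lam, penalize_diagonal) <= tol:
            break
        if n_iter % 10 == 0:
            # polish the current support; the proximal sweep resumes if the
            # refined point still violates the zero-set conditions
            omega_r, path_r = _newton_refine(S, omega, lam, penalize_diagonal, obj)
            if path_r:
                omega, obj = omega_r, path_r[-1]
                path.extend(path_r)
                y, t_k = omega.copy(), 1.0
            if kkt_residual(S, omega, lam, penalize_diagonal) <= tol:
                break
    else:
        raise RuntimeError(
            f"graphical lasso did not converge in {max_iter} iterations "
            f"(KKT residual {kkt_residual(S, omega, lam, penalize_diagonal):.2e})"
        )
    return PrecisionEstimate(matrix=omega, penalty=float(lam),
                             n_iter=n_iter, objective_path=path)


def select_lambda_bic(
    epochs,
    grid: Sequence[float] = (0.02, 0.05, 0.1, 0.2, 0.4),
    spec: KernelSpec = KernelSpec(),
    center: bool = True,
) -> float:
    """Coarse BIC selection of the graphical-lasso penalty on pooled data.

    Averages the per-epoch (correlation-rescaled) averaged covariances into
    one pooled matrix, fits the graphical lasso along ``grid`` and scores
    each fit with BIC = n*(Tr(S Omega) - log det Omega) + log(n)*|support|,
    n being the pooled count of time points. One global penalty keeps edge
    scales comparable across epochs.
    """
    if isinstance(epochs, EpochSet):
        epochs = epochs.epochs
    mats = []
    n_obs = 0
    for e in epochs:
        X = e.data if isinstance(e, Epoch) else np.asarray(e, float)
        S = averaged_covariance(X, spec=spec, center=center).matrix
        sd = np.sqrt(np.maximum(np.diag(S), 1e-12))
        mats.append(S / np.outer(sd, sd))
        n_obs += X.shape[1]
    S_pool = np.mean(mats, axis=0)
    best_lam, best_bic = None, np.inf
    for lam in grid:
        est = graphical_lasso(S_pool, lam)
        nll = float(np.tensordot(S_pool, est.matrix)
                    - 2.0 * np.log(np.diag(np.linalg.cholesky(est.matrix))).sum())
        bic = n_obs * nll + np.log(n_obs) * len(est.support)
        if bic < best_bic:
            best_bic, best_lam = bic, float(lam)
    return best_lam


def partial_correlation(omega: PrecisionEstimate | np.ndarray) -> np.ndarray:
    """Partial-correlation matrix W, W_ij = -omega_ij / sqrt(omega_ii omega_jj).

    The diagonal is 1 and the zero pattern matches the precision support.
    """
    M = omega.matrix if isinstance(omega, PrecisionEstimate) else np.asarray(omega, float)
    d = np.diag(M)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be strictly positive")
    inv_sd = 1.0 / np.sqrt(d)
    W = -M * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(W, 1.0)
    return W


def vectorize_upper(W: np.ndarray) -> np.ndarray:
    """Upper-triangle entries read by row: W_12..W_1p, W_23..W_2p, ...

    Length d = p(p-1)/2.
    """
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if W.shape[0] < 2:
        raise ValueError("need at least two channels to form edges")
    iu, ju = np.triu_indices(W.shape[0], k=1)
    return W[iu, ju].copy()


def edge_names_for(channel_labels: Sequence[str]) -> list[str]:
    """Edge labels aligned index-for-index with :func:`vectorize_upper`."""
    p = len(channel_labels)
    iu, ju = np.triu_indices(p, k=1)
    return [f"{channel_labels[i]}--{channel_labels[j]}" for i, j in zip(iu, ju)]


def epoch_to_network_vector(
    epoch: Epoch | np.ndarray,
    lam: float = 0.1,
    spec: KernelSpec = KernelSpec(),
    center: bool = True,
    scale_covariance: bool = True,
    edge_measure: str = "partial_correlation",
    **glasso_kwargs,
) -> np.ndarray:
    """One epoch -> vectorized sparse connectivity (length p(p-1)/2)."""
    X = epoch.data if isinstance(epoch, Epoch) else np.asarray(epoch, float)
    S = averaged_covariance(X, spec=spec, center=center).matrix
    if scale_covariance:
        sd = np.sqrt(np.maximum(np.diag(S), 1e-12))
        S = S / np.outer(sd, sd)
    est = graphical_lasso(S, lam=lam, **glasso_kwargs)
    if edge_measure == "partial_correlation":
        W = partial_correlation(est)
    elif edge_measure == "precision":
        W = est.matrix
    else:
        raise ValueError("edge_measure must be 'partial_correlation' or 'precision'")
    return vectorize_upper(W)


class DynamicConnectivity(BaseEstimator, TransformerMixin):
    """Transformer from labeled epochs to the network predictor matrix.

    Parameters
    ----------
    lam : float
        Graphical-lasso penalty, shared by all epochs so edge scales are
        comparable. Applied to the correlation-rescaled averaged covariance
        when ``scale_covariance``.
    feature_mode : {"network", "raw", "combined"}
        ``network`` gives d = p(p-1)/2 partial-correlation edges; ``raw``
        flattens each epoch row-major to p*q values; ``combined``
        concatenates [network | raw].
    kernel_spec : KernelSpec
        Time-smoothing kernel; default Gaussian with h = q**(1/3).
    center : bool
        Mean-center each electrode within the epoch before covariance.
    edge_measure : {"partial_correlation", "precision"}
        Strength measure placed on the edges.

    The transformer is stateless apart from parameter validation; ``fit``
    records the channel count so ``edge_names_`` can be exposed.
    """

    def __init__(self, lam: float = 0.1, feature_mode: str = "network",
                 kernel_spec: KernelSpec = KernelSpec(), center: bool = True,
                 scale_covariance: bool = True,
                 edge_measure: str = "partial_correlation",
                 glasso_tol: float = 1e-5, glasso_max_iter: int = 500):
        self.lam = lam
        self.feature_mode = feature_mode
        self.kernel_spec = kernel_spec
        self.center = center
        self.scale_covariance = scale_covariance
        self.edge_measure = edge_measure
        self.glasso_tol = glasso_tol
        self.glasso_max_iter = glasso_max_iter

    @staticmethod
    def _as_array(epochs: EpochSet | Sequence[Epoch] | np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        if isinstance(epochs, EpochSet):
            epochs = epochs.epochs
        if isinstance(epochs, np.ndarray):
            if epochs.ndim != 3:
                raise ValueError("epoch array must be n x p x q")
            return epochs.astype(float), None
        data = np.stack([e.data for e in epochs])
        labels = np.array([e.label for e in epochs], dtype=int)
        return data, labels

    def fit(self, X: EpochSet | Sequence[Epoch] | np.ndarray, y=None):
        if self.feature_mode not in ("network", "raw", "combined"):
            raise ValueError("feature_mode must be network, raw or combined")
        data, _ = self._as_array(X)
        self.n_channels_ = data.shape[1]
        self.n_times_ = data.shape[2]
        self.edge_names_ = edge_names_for([f"ch{i}" for i in range(self.n_channels_)])
        return self

    def transform(self, X: EpochSet | Sequence[Epoch] | np.ndarray) -> np.ndarray:
        data, _ = self._as_array(X)
        if data.shape[1] != getattr(self, "n_channels_", data.shape[1]):
            raise ValueError("channel count differs from fit")
        blocks = []
        if self.feature_mode in ("network", "combined"):
            net = np.stack([
                epoch_to_network_vector(
                    x, lam=self.lam, spec=self.kernel_spec, center=self.center,
                    scale_covariance=self.scale_covariance,
                    edge_measure=self.edge_measure,
                    tol=self.glasso_tol, max_iter=self.glasso_max_iter,
                )
                for x in data
            ])
            blocks.append(net)
        if self.feature_mode in ("raw", "combined"):
            blocks.append(data.reshape(data.shape[0], -1))
        return np.hstack(blocks)


def build_predictor_matrix(
    epochs: EpochSet,
    mode: str = "network",
    lam: float = 0.1,
    spec: KernelSpec = KernelSpec(),
    center: bool = True,
    channel_labels: Sequence[str] | None = None,
    **kwargs,
) -> NetworkPredictorMatrix:
    """Stack per-epoch feature vectors, preictal block first.

    Thin wrapper over :class:`DynamicConnectivity` that also orders rows
    (preictal then interictal), attaches labels Z and names the edges.
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch set")
    ordered = sorted(epochs.epochs, key=lambda e: (-e.label, e.epoch_index))
    tf = DynamicConnectivity(lam=lam, feature_mode=mode, kernel_spec=spec,
                             center=center, **kwargs)
    V = tf.fit(ordered).transform(ordered)
    Z = np.array([e.label for e in ordered], dtype=int)
    p = epochs.shape[0]
    labels = list(channel_labels) if channel_labels is not None else [f"ch{i}" for i in range(p)]
    if len(labels) != p:
        raise ValueError("channel_labels length differs from epoch channel count")
    names = edge_names_for(labels) if mode in ("network", "combined") else []
    return NetworkPredictorMatrix(V=V, Z=Z, edge_names=names, feature_mode=mode)
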