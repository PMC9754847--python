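"""Matrix-normal EEG simulator with planted class-differential networks.

Epochs are drawn from X ~ MN(M, Sigma_T (x) Sigma_S): an AR(1) temporal
covariance Sigma_T (entries rho^|i-j|) and a spatial covariance that is the
inverse of a sparse precision matrix. The preictal and interictal classes
share a baseline Erdos-Renyi precision support; the preictal class carries
``n_diff`` extra edges whose identities are recorded exactly, so feature
selection can be scored against ground truth. Small toy continuous
recordings with seizure annotations exercise the state-labeling and
epoching arithmetic end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epoching import Epoch, EpochSet
from .io import Recording, SeizureAnnotation

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_precision_pair",
    "sample_matrix_normal",
    "simulate_epoch_set",
    "simulate_recording",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the planted-network benchmark.

    delta is the planted off-diagonal magnitude on the partial-correlation
    scale; rho_T the AR(1) temporal autocorrelation mimicking the smoothness
    of per-second-averaged EEG; noise_sd adds white observation noise on top
    of the matrix-normal signal.
    """

    p: int = 10
    q: int = 60
    n1: int = 60
    n2: int = 60
    edge_prob: float = 0.1
    n_diff: int = 5
    delta: float = 0.4
    rho_T: float = 0.5
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.edge_prob <= 1:
            raise ValueError("edge_prob must lie in [0, 1]")
        if not abs(self.delta) < 1:
            raise ValueError("|delta| must be < 1 (partial-correlation scale)")
        if not abs(self.rho_T) < 1:
            raise ValueError("|rho_T| must be < 1")
        if self.n_diff > self.p * (self.p - 1) // 2:
            raise ValueError("n_diff exceeds the number of possible edges")
        if self.p < 2 or self.q < 2:
            raise ValueError("need p >= 2 and q >= 2")
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("class sizes must be non-negative")


@dataclass
class GroundTruth:
    """The two planted precision matrices and their differing edge set."""

    omega_pre: np.ndarray
    omega_inter: np.ndarray
    diff_edges: set[tuple[int, int]] = field(default_factory=set)


def _ar1_covariance(q: int, rho: float) -> np.ndarray:
    idx = np.arange(q)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def make_precision_pair(cfg: SimulationConfig) -> GroundTruth:
    """Build SPD preictal/interictal precision matrices differing in n_diff edges.

    A shared Erdos-Renyi support gets off-diagonal entries of magnitude
    ``a = 1`` with random signs; ``n_diff`` extra signed edges go to the
    preictal matrix only. Both matrices receive one common diagonal value

        s = a * max(1/delta, |lambda_min(pattern)| + 0.1)

    which guarantees positive definiteness and, whenever the first term
    binds (the usual sparse case), makes the planted partial correlations
    equal +/-delta exactly. Sharing the diagonal keeps ``diff_edges``
    exactly the off-diagonal positions where the matrices differ.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.p
    iu, ju = np.triu_indices(p, k=1)
    n_pairs = iu.size

    base = rng.random(n_pairs) < cfg.edge_prob
    free = np.flatnonzero(~base)
    if free.size < cfg.n_diff:
        raise ValueError(
            f"cannot place n_diff={cfg.n_diff} extra edges: only {free.size} free pairs"
        )
    extra = rng.choice(free, size=cfg.n_diff, replace=False)

    a = 1.0
    signs = rng.choice([-1.0, 1.0], size=n_pairs)

    def assemble(mask: np.ndarray) -> np.ndarray:
        A = np.zeros((p, p))
        A[iu[mask], ju[mask]] = a * signs[mask]
        return A + A.T

    mask_inter = base
    mask_pre = base.copy()
    mask_pre[extra] = True
    A_pre = assemble(mask_pre)
    A_inter = assemble(mask_inter)

    lam_min = min(np.linalg.eigvalsh(A_pre).min(), np.linalg.eigvalsh(A_inter).min())
    s = a * max(1.0 / abs(cfg.delta) if cfg.delta != 0 else 0.0, abs(lam_min) + 0.1)
    if s == 0.0:  # delta == 0 with empty support
        s = 1.0
    omega_pre = A_pre + s * np.eye(p)
    omega_inter = A_inter + s * np.eye(p)

    diff = {(int(i), int(j)) for i, j in zip(iu[extra], ju[extra])}
    return GroundTruth(omega_pre=omega_pre, omega_inter=omega_inter, diff_edges=diff)


def _chol_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be a symmetric square matrix")
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite") from exc


def sample_matrix_normal(M: np.ndarray, sigma_S: np.ndarray, sigma_T: np.ndarray,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """One draw X = M + A G B' with AA' = sigma_S, BB' = sigma_T, G iid N(0,1).

    vec(X - M) then has covariance sigma_T (x) sigma_S (columns stacked).
    """
    A = _chol_spd(sigma_S, "sigma_S")
    B = _chol_spd(sigma_T, "sigma_T")
    M = np.asarray(M, float)
    p, q = A.shape[0], B.shape[0]
    if M.shape != (p, q):
        raise ValueError(f"mean must have shape ({p}, {q})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = rng.standard_normal((p, q))
    return M + A @ G @ B.T


def simulate_epoch_set(cfg: SimulationConfig) -> tuple[EpochSet, GroundTruth]:
    """Draw n1 preictal + n2 interictal matrix-normal epochs with noise.

    Preictal epochs use Sigma_S = omega_pre^{-1}, interictal ones
    omega_inter^{-1}; both share the AR(1) Sigma_T and receive iid
    N(0, noise_sd^2) observation noise. Deterministic given cfg.seed.
    """
    truth = make_precision_pair(cfg)
    sigma_T = _ar1_covariance(cfg.q, cfg.rho_T)
    sigma_pre = np.linalg.inv(truth.omega_pre)
    sigma_inter = np.linalg.inv(truth.omega_inter)
    M = np.zeros((cfg.p, cfg.q))

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    epochs: list[Epoch] = []
    idx = 0
    for label, n, sig in ((1, cfg.n1, sigma_pre), (0, cfg.n2, sigma_inter)):
        for _ in range(n):
            X = sample_matrix_normal(M, sig, sigma_T, seed=rng)
            if cfg.noise_sd > 0:
                X = X + cfg.noise_sd * rng.standard_normal(X.shape)
            epochs.append(Epoch(data=X, label=label, patient_id="sim",
                                epoch_index=idx, origin_sec=60.0 * idx))
            idx += 1
    return EpochSet(epochs=epochs), truth


def simulate_recording(plan: list[tuple[float, float]], duration_sec: float,
                       fs: float = 256.0, p: int = 21,
                       seed: int = 0) -> tuple[Recording, SeizureAnnotation]:
    """Gaussian-noise recording with a seizure plan, for epoching arithmetic.

    The waveform carries no class signal; the pair exists to exercise
    state labeling and epoch extraction end to end.
    """
    for onset, offset in plan:
        if not (0 <= onset < offset <= duration_sec):
            raise ValueError(f"seizure ({onset}, {offset}) outside [0, {duration_sec}]")
    ann = SeizureAnnotation(events=list(plan))  # validates sorting/overlap
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("fs must be an integer number of samples per second")
    n_samples = int(round(duration_sec * fs))
    rng = np.random.default_rng(seed)
    signals = rng.standard_normal((p, n_samples))
    rec = Recording(
        channel_labels=[f"CH{i:02d}" for i in range(p)],
        sampling_rate=float(fs), signals=signals, start_time_sec=0.0,
        montage="referential",
    )
    return rec, ann
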