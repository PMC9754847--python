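"""Bootstrap-ensembled L1 logistic classification of preictal vs interictal.

The ensemble draws B class-stratified bootstrap resamples (n1 preictal and
n2 interictal epochs with replacement), fits an L1-penalized logistic
regression to each, and averages the B predicted probabilities into P_hat_B.
The selection frequency

    psi_i = (1/B) * sum_b I(beta_i^(b) != 0)

is the per-edge importance weight: the closer to 1, the more consistently
the edge is needed to separate the two states.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from scipy.stats import rankdata

from .connectivity import NetworkPredictorMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapLassoLogistic",
    "EdgeImportance",
    "PredictionMetrics",
    "fit_ensemble",
    "predict_probability",
    "edge_importance",
    "select_cutoff",
    "compute_metrics",
    "cross_validate",
]


@dataclass
class EdgeImportance:
    """Bootstrap selection frequencies psi with a stable descending ranking."""

    psi: np.ndarray
    edge_names: list[str]
    ranking: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "edge_name": [self.edge_names[i] for i in self.ranking],
            "psi": self.psi[self.ranking],
        })


@dataclass
class PredictionMetrics:
    """SENS / FDR / AUC plus the accuracy-maximizing cutoff and confusion."""

    sens: float
    fdr: float
    auc: float
    cutoff: float
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN)
    protocol: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {
            "sens": self.sens, "fdr": self.fdr, "auc": self.auc,
            "cutoff": self.cutoff,
            "confusion": {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
            "protocol": self.protocol,
        }


class BootstrapLassoLogistic(ClassifierMixin, BaseEstimator):
    """Bootstrap-ensembled L1-penalized logistic regression.

    Parameters
    ----------
    B : int
        Number of bootstrap resamples / ensemble members.
    lambda_rule : {"cv_once", "fixed"}
        ``cv_once`` selects the penalty once by stratified cross-validation
        on the full training matrix and reuses it for every bootstrap fit;
        ``fixed`` uses ``C`` directly.
    C : float
        Inverse penalty strength for ``lambda_rule="fixed"`` (sklearn
        convention; the L1 penalty is 1/C per fit).
    random_state : int
        Seeds bootstrap draws and the CV split; same seed, same fit.
    nonzero_tol : float
        |coefficient| threshold (original column scale) for the selection
        indicator in psi.

    Attributes
    ----------
    coefs_ : ndarray of shape (B, d)
        Per-bootstrap coefficients on the original column scale.
    intercepts_ : ndarray of shape (B,)
    selection_frequency_ : ndarray of shape (d,)
        psi, the fraction of fits in which each column was selected.
    mean_, scale_ : ndarray of shape (d,)
        Training-column standardization parameters.
    C_ : float
        Penalty actually used (after CV when ``cv_once``).
    """

    def __init__(self, B: int = 100, lambda_rule: str = "cv_once", C: float = 1.0,
                 random_state: int = 0, nonzero_tol: float = 1e-8,
                 cv_folds: int = 5):
        self.B = B
        self.lambda_rule = lambda_rule
        self.C = C
        self.random_state = random_state
        self.nonzero_tol = nonzero_tol
        self.cv_folds = cv_folds

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (epochs x features)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.lambda_rule not in ("cv_once", "fixed"):
            raise ValueError("lambda_rule must be 'cv_once' or 'fixed'")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("both classes (0 interictal, 1 preictal) must be present")
        self.classes_ = classes
        n, d = X.shape

        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.kept_ = sd > 0
        if not self.kept_.all():
            logger.warning("dropping %d zero-variance column(s)", (~self.kept_).sum())
        self.scale_ = np.where(self.kept_, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_
        Xs = Xs[:, self.kept_]

        ss = np.random.SeedSequence(self.random_state)
        cv_seed, boot_seed = [int(s) for s in ss.generate_state(2) % (2**31 - 1)]

        if self.lambda_rule == "cv_once":
            folds = min(self.cv_folds, int(np.bincount(y).min()))
            if folds < 2:
                raise ValueError("cv_once needs at least 2 epochs per class")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                # LogisticRegressionCV's penalty API is mid-transition;
                # behavior pinned here. Log-loss scoring (a proper scoring
                # rule) is used for penalty selection: under weak signal it
                # prefers the better-calibrated sparser model where accuracy
                # cannot discriminate between penalty levels.
                warnings.simplefilter("ignore", FutureWarning)
                warnings.filterwarnings(
                    "ignore", message=".*penalty.*", category=UserWarning)
                cv = LogisticRegressionCV(
                    Cs=np.logspace(-2, 2, 10), penalty="l1", solver="liblinear",
                    cv=StratifiedKFold(folds, shuffle=True, random_state=cv_seed),
                    intercept_scaling=100.0, max_iter=1000,
                    scoring="neg_log_loss", random_state=cv_seed,
                )
                cv.fit(Xs, y)
            self.C_ = float(cv.C_[0])
        else:
            self.C_ = float(self.C)
        self.lambda_logistic_ = 1.0 / self.C_

        idx1 = np.flatnonzero(y == 1)
        idx0 = np.flatnonzero(y == 0)
        rng = np.random.default_rng(boot_seed)
        coefs = np.zeros((self.B, d))
        intercepts = np.zeros(self.B)
        # fixed solver random_state: liblinear's internal shuffling must not
        # break the bit-identical-given-seed contract
        base = LogisticRegression(penalty="l1", C=self.C_, solver="liblinear",
                                  intercept_scaling=100.0, max_iter=1000,
                                  random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            warnings.filterwarnings(
                "ignore", message=".*penalty.*", category=UserWarning)
            for b in range(self.B):
                rows = np.concatenate([
                    rng.choice(idx1, size=idx1.size, replace=True),
                    rng.choice(idx0, size=idx0.size, replace=True),
                ])
                m = base.fit(Xs[rows], y[rows])
                beta_std = np.zeros(d)
                beta_std[self.kept_] = m.coef_.ravel()
                # map back to the original column scale
                coefs[b] = beta_std / self.scale_
                intercepts[b] = float(m.intercept_[0]) - float(coefs[b] @ self.mean_)

        self.coefs_ = coefs
        self.intercepts_ = intercepts
        self.selection_frequency_ = (
            (np.abs(coefs) > self.nonzero_tol).mean(axis=0)
        )
        self.n_features_in_ = d
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Column 1 is P_hat_B, the mean of the B per-model probabilities."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape}"
            )
        logits = X @ self.coefs_.T + self.intercepts_  # (m, B)
        p = (1.0 / (1.0 + np.exp(-logits))).mean(axis=1)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= cutoff).astype(int)

    def edge_importance(self, edge_names: list[str] | None = None) -> EdgeImportance:
        """psi per feature; ties in the ranking break toward lower index."""
        psi = self.selection_frequency_
        if edge_names is None:
            edge_names = [f"x{i}" for i in range(psi.size)]
        order = np.lexsort((np.arange(psi.size), -psi))
        return EdgeImportance(psi=psi.copy(), edge_names=list(edge_names),
                              ranking=order)


def fit_ensemble(V: NetworkPredictorMatrix | np.ndarray, B: int = 100,
                 lambda_rule: str = "cv_once", seed: int = 0,
                 y: np.ndarray | None = None, **kwargs) -> BootstrapLassoLogistic:
    """Fit the bootstrap lasso-logistic ensemble on a predictor matrix."""
    if isinstance(V, NetworkPredictorMatrix):
        X, y = V.V, V.Z
    else:
        X = np.asarray(V, float)
        if y is None:
            raise ValueError("labels y required with a plain array")
    model = BootstrapLassoLogistic(B=B, lambda_rule=lambda_rule,
                                   random_state=seed, **kwargs)
    return model.fit(X, y)


def predict_probability(model: BootstrapLassoLogistic, rows: np.ndarray) -> np.ndarray:
    """P_hat_B for each row: the ensemble-averaged preictal probability."""
    return model.predict_proba(np.asarray(rows, float))[:, 1]


def edge_importance(model: BootstrapLassoLogistic,
                    edge_names: list[str] | None = None) -> EdgeImportance:
    """Selection-frequency weights psi from a fitted ensemble."""
    return model.edge_importance(edge_names)


def select_cutoff(probs: np.ndarray, labels: np.ndarray) -> float:
    """Probability cutoff maximizing accuracy, by exhaustive candidates.

    Candidates are the midpoints between adjacent sorted unique
    probabilities plus {0, 1}; a row is positive when prob >= cutoff. Ties
    in accuracy break toward the smallest cutoff.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    uniq = np.unique(probs)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    best_cut, best_acc = 0.0, -1.0
    for c in np.sort(candidates):
        acc = float(((probs >= c).astype(int) == labels).mean())
        if acc > best_acc + 1e-12:
            best_acc, best_cut = acc, float(c)
    return best_cut


def _auc_rank(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank-sum statistic, average ranks for ties."""
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(probs)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compute_metrics(probs: np.ndarray, labels: np.ndarray,
                    cutoff: float) -> PredictionMetrics:
    """SENS, FDR and rank-based AUC at a given probability cutoff.

    SENS = TP/(TP+FN); FDR = FP/(TP+FP), defined as 0 when nothing is
    predicted positive; positive means prob >= cutoff.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pred = (probs >= cutoff).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    auc = _auc_rank(probs, labels)
    return PredictionMetrics(sens=sens, fdr=fdr, auc=auc, cutoff=float(cutoff),
                             confusion=(tp, fp, tn, fn))


def cross_validate(
    epochs_or_V,
    mode: str = "network",
    k: int = 5,
    B: int = 100,
    lam: float = 0.1,
    spec=None,
    seed: int = 0,
    center: bool = True,
    lambda_rule: str = "cv_once",
    channel_labels=None,
) -> tuple[PredictionMetrics, EdgeImportance]:
    """Stratified k-fold evaluation with pooled out-of-fold probabilities.

    Stage-1 connectivity features are per-epoch and unsupervised under a
    fixed global penalty, so the feature matrix is computed once and rows
    are indexed per fold; the ensemble (standardization, penalty CV,
    bootstraps) is fit on training rows only. The cutoff is chosen on the
    pooled out-of-fold probabilities and the metrics are computed from the
    pooled predictions. psi comes from a final refit on all rows.
    """
    from .connectivity import EpochSet, KernelSpec, build_predictor_matrix

    if isinstance(epochs_or_V, NetworkPredictorMatrix):
        pm = epochs_or_V
    elif isinstance(epochs_or_V, EpochSet):
        pm = build_predictor_matrix(
            epochs_or_V, mode=mode, lam=lam,
            spec=spec if spec is not None else KernelSpec(),
            center=center, channel_labels=channel_labels,
        )
    else:
        raise TypeError("expected an EpochSet or NetworkPredictorMatrix")
    X, y = pm.V, pm.Z
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= k={k} epochs; have n1={counts[1]}, n2={counts[0]}"
        )

    ss = np.random.SeedSequence(seed)
    fold_seed, fit_seed, final_seed = [int(s) for s in ss.generate_state(3) % (2**31 - 1)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
    oof = np.empty(len(y))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        model = BootstrapLassoLogistic(B=B, lambda_rule=lambda_rule,
                                       random_state=fit_seed + f).fit(X[tr], y[tr])
        oof[te] = predict_probability(model, X[te])

    cutoff = select_cutoff(oof, y)
    metrics = compute_metrics(oof, y, cutoff)
    metrics.protocol = {
        "evaluation": "stratified k-fold, pooled out-of-fold probabilities",
        "k": k, "B": B, "lambda_rule": lambda_rule, "feature_mode": pm.feature_mode,
        "glasso_lambda": lam, "seed": seed,
        "n1": int(counts[1]), "n2": int(counts[0]),
    }
    final = BootstrapLassoLogistic(B=B, lambda_rule=lambda_rule,
                                   random_state=final_seed).fit(X, y)
    names = pm.edge_names if pm.edge_names else None
    if names is not None and len(names) != X.shape[1]:
        names = names + [f"raw{i}" for i in range(X.shape[1] - len(names))]
    psi = final.edge_importance(names)
    return metrics, psi
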