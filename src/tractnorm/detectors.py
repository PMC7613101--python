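"""Anomaly scorers over normative tract-profile features.

Three unsupervised detectors trained on healthy controls only:

* **z-score** — per-feature standardization against the normative mean and
  standard deviation; a subject's anomaly score is the mean |z| (default)
  or mean signed z across features.
* **PCA + Mahalanobis** — project onto the leading principal components
  retaining >= 85% of the normative variance, then measure the
  covariance-aware distance to the normative mean.  The quadratic form
  ``(x - mu)' C^-1 (x - mu)`` is computed and reported as its square root
  (the classical Mahalanobis distance; a monotone transform, so rankings
  and AUCs are unchanged).
* **autoencoder** — a symmetric five-layer fully connected network
  (n -> n/2 -> n/4 -> n/2 -> n, ceiling division) with ReLU hidden
  activations, a tanh output layer, an l1 activity penalty (1e-5) on the
  bottleneck, trained with Adam on mean squared error for 25 epochs at
  batch size 24 and learning rate 1e-3.  The anomaly score of a subject is
  the mean absolute error (MAE) between input and reconstruction.

A supervised SVM baseline (repeated stratified cross-validated AUC with
per-fold grid search) is provided for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold
from sklearn.svm import SVC

from .exceptions import (
    CohortSizeError,
    DataError,
    DegenerateFeatureError,
    DimensionError,
    ParameterError,
)
from .io import FeatureMatrix


def _matrix(m) -> np.ndarray:
    return m.data if isinstance(m, FeatureMatrix) else np.asarray(m, dtype=float)


# ---------------------------------------------------------------------------
# z-score
# ---------------------------------------------------------------------------

@dataclass
class NormativeStats:
    """Per-feature mean and (n-1) standard deviation of the healthy cohort."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, train: FeatureMatrix | np.ndarray) -> "NormativeStats":
        X = _matrix(train)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            bad = np.flatnonzero(sd <= 0)[:5].tolist()
            raise DegenerateFeatureError(
                f"zero-variance feature(s) at column(s) {bad}"
            )
        return cls(mu, sd)


def score_zscore(
    stats: NormativeStats,
    m: FeatureMatrix | np.ndarray,
    mode: str = "absolute",
) -> np.ndarray:
    """Mean per-feature z relative to the normative stats, one score per row."""
    if mode not in ("absolute", "signed"):
        raise ParameterError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    X = _matrix(m)
    if X.shape[1] != stats.mean.shape[0]:
        raise DimensionError(
            f"{X.shape[1]} features vs {stats.mean.shape[0]} in stats"
        )
    z = (X - stats.mean) / stats.std
    return np.abs(z).mean(axis=1) if mode == "absolute" else z.mean(axis=1)


# ---------------------------------------------------------------------------
# PCA + Mahalanobis
# ---------------------------------------------------------------------------

@dataclass
class MahalanobisModel:
    pca: PCA
    mean: np.ndarray          # training mean in component space
    cov: np.ndarray           # component-space covariance (regularized)
    cov_inv: np.ndarray

    @property
    def n_components(self) -> int:
        return self.pca.n_components_


def fit_pca_mahalanobis(
    train: FeatureMatrix | np.ndarray,
    variance_threshold: float = 0.85,
    ridge: float = 1e-6,
) -> MahalanobisModel:
    """Fit PCA (smallest #components with cumulative EVR >= threshold) and
    the component-space normative covariance.

    Near-singular covariances are ridge-regularized by
    ``ridge * trace(C)/d`` on the diagonal.
    """
    X = _matrix(train)
    if not 0 < variance_threshold <= 1:
        raise ParameterError(f"variance_threshold in (0,1], got {variance_threshold}")
    n_comp = None if variance_threshold >= 1 else variance_threshold
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    d = scores.shape[1]
    if len(X) <= d:
        raise CohortSizeError(
            f"{len(X)} training subjects <= {d} retained components"
        )
    mu = scores.mean(axis=0)
    C = np.atleast_2d(np.cov(scores, rowvar=False, ddof=1))
    if np.linalg.cond(C) > 1e10:
        C = C + ridge * np.trace(C) / d * np.eye(d)
    try:
        C_inv = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise DataError(f"singular covariance after regularization: {e}") from e
    return MahalanobisModel(pca, mu, C, C_inv)


def score_mahalanobis(model: MahalanobisModel, m: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Mahalanobis distance of each row to the normative mean in PC space."""
    X = _matrix(m)
    if X.shape[1] != model.pca.n_features_in_:
        raise DimensionError(
            f"{X.shape[1]} features vs model's {model.pca.n_features_in_}"
        )
    s = model.pca.transform(X) - model.mean
    q = np.einsum("ij,jk,ik->i", s, model.cov_inv, s)
    return np.sqrt(np.maximum(q, 0.0))


# ---------------------------------------------------------------------------
# Autoencoder
# ---------------------------------------------------------------------------

def build_layer_widths(n_features: int) -> list[int]:
    """Symmetric five-layer widths [n, ceil(n/2), ceil(n/4), ceil(n/2), n]."""
    if n_features < 4:
        raise ParameterError(
            f"autoencoder needs >= 4 features, got {n_features}"
        )
    h1 = -(-n_features // 2)
    h2 = -(-h1 // 2)
    return [n_features, h1, h2, h1, n_features]


@dataclass
class AutoencoderSpec:
    """Hyperparameters of the normative autoencoder."""

    epochs: int = 25
    batch_size: int = 24
    learning_rate: float = 1e-3
    l1_bottleneck: float = 1e-5
    validation_split: float = 0.1
    seed: int = 0


@dataclass
class AutoencoderModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    widths: list[int]
    history: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.widths[0]

    def _forward(self, X: np.ndarray):
        a = X
        acts = [a]
        n_layers = len(self.weights)
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = np.tanh(z) if li == n_layers - 1 else np.maximum(z, 0.0)
            acts.append(a)
        return acts

    def reconstruct(self, m: FeatureMatrix | np.ndarray) -> np.ndarray:
        X = _matrix(m)
        if X.shape[1] != self.n_features:
            raise DimensionError(
                f"{X.shape[1]} features vs model's {self.n_features}"
            )
        return self._forward(X)[-1]


def fit_autoencoder(
    train: FeatureMatrix | np.ndarray,
    spec: AutoencoderSpec | None = None,
) -> AutoencoderModel:
    """Train the normative autoencoder on (preprocessed) control data.

    Trains for exactly ``spec.epochs`` epochs with no early stopping; an
    inner ``validation_split`` fraction is held out purely to monitor the
    loss.  Fully deterministic for a fixed ``spec.seed``.
    """
    spec = spec or AutoencoderSpec()
    X = _matrix(train)
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in training matrix")
    n, p = X.shape
    if n < 3:
        raise CohortSizeError(f"need >= 3 training subjects, got {n}")
    widths = build_layer_widths(p)
    rng = np.random.default_rng(spec.seed)

    # inner monitoring split
    perm = rng.permutation(n)
    n_val = max(1, int(round(spec.validation_split * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, X_val = X[tr_idx], X[val_idx]

    # uniform fan-in initialization
    Ws, bs = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        Ws.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        bs.append(rng.uniform(-bound, bound, size=fan_out))

    # Adam state
    mW = [np.zeros_like(W) for W in Ws]
    vW = [np.zeros_like(W) for W in Ws]
    mb = [np.zeros_like(b) for b in bs]
    vb = [np.zeros_like(b) for b in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    model = AutoencoderModel(Ws, bs, widths)
    bottleneck = len(Ws) // 2  # index of the activation after layer 2

    def mse(A: np.ndarray) -> float:
        out = model._forward(A)[-1]
        return float(np.mean((out - A) ** 2))

    hist_tr, hist_val = [], []
    m_tr = len(X_tr)
    for _epoch in range(spec.epochs):
        order = rng.permutation(m_tr)
        for start in range(0, m_tr, spec.batch_size):
            batch = X_tr[order[start:start + spec.batch_size]]
            B = len(batch)
            acts = model._forward(batch)
            out = acts[-1]
            # d(MSE)/d(out); MSE averaged over batch and features
            delta = 2.0 * (out - batch) / (B * p)
            # through tanh
            delta = delta * (1.0 - out ** 2)
            gW = [None] * len(Ws)
            gb = [None] * len(Ws)
            for li in range(len(Ws) - 1, -1, -1):
                a_prev = acts[li]
                gW[li] = a_prev.T @ delta
                gb[li] = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ Ws[li].T) * (acts[li] > 0)
                    if li == bottleneck:
                        # l1 activity penalty on bottleneck: weight * mean over
                        # batch of sum_units |a|; relu activations are >= 0
                        delta = delta + (
                            spec.l1_bottleneck / B * np.sign(acts[li])
                        ) * (acts[li] > 0)
            t += 1
            corr = np.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
            for li in range(len(Ws)):
                mW[li] = beta1 * mW[li] + (1 - beta1) * gW[li]
                vW[li] = beta2 * vW[li] + (1 - beta2) * gW[li] ** 2
                Ws[li] -= spec.learning_rate * corr * mW[li] / (np.sqrt(vW[li]) + eps)
                mb[li] = beta1 * mb[li] + (1 - beta1) * gb[li]
                vb[li] = beta2 * vb[li] + (1 - beta2) * gb[li] ** 2
                bs[li] -= spec.learning_rate * corr * mb[li] / (np.sqrt(vb[li]) + eps)
        hist_tr.append(mse(X_tr))
        hist_val.append(mse(X_val))

    model.history = {"train_loss": hist_tr, "val_loss": hist_val}
    return model


def reconstruction_errors(
    model: AutoencoderModel, m: FeatureMatrix | np.ndarray
) -> np.ndarray:
    """Signed per-subject, per-feature error x - x_hat (positive where the
    network learned a smaller value than the input)."""
    X = _matrix(m)
    return X - model.reconstruct(X)


def score_mae(model: AutoencoderModel, m: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-subject mean absolute reconstruction error (the anomaly score)."""
    return np.abs(reconstruction_errors(model, m)).mean(axis=1)


# ---------------------------------------------------------------------------
# Supervised SVM baseline
# ---------------------------------------------------------------------------

SVM_PARAM_GRID = [
    {"kernel": ["rbf"], "C": [1, 10, 100, 1000],
     "gamma": [1e-3, 1e-2, 1e-1, 1, 1e1, 1e2, 1e3]},
    {"kernel": ["linear"], "C": [1, 10, 100, 1000]},
]


@dataclass
class SvmBaselineResult:
    mean_auc: float
    sd_auc: float
    fold_aucs: np.ndarray
    n_param_combinations: int


def fit_svm_baseline(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_repeats: int = 10,
    n_splits: int = 5,
) -> SvmBaselineResult:
    """Repeated stratified cross-validated AUC of a class-weight-balanced SVM
    with per-fold grid search over kernel, C and gamma."""
    X = _matrix(features)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ParameterError(f"need exactly 2 classes, got {classes.tolist()}")
    from sklearn.metrics import roc_auc_score

    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                 random_state=seed)
    aucs = []
    n_combos = sum(
        int(np.prod([len(v) for v in g.values()])) for g in SVM_PARAM_GRID
    )
    for tr, te in cv.split(X, y):
        if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
            raise CohortSizeError("a CV fold is missing one class")
        gs = GridSearchCV(
            SVC(class_weight="balanced"), SVM_PARAM_GRID,
            scoring="roc_auc", cv=3, n_jobs=1,
        )
        gs.fit(X[tr], y[tr])
        scores = gs.decision_function(X[te])
        aucs.append(roc_auc_score(y[te], scores))
    aucs = np.asarray(aucs)
    return SvmBaselineResult(float(aucs.mean()), float(aucs.std(ddof=1)),
                             aucs, n_combos)
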