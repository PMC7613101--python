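"""Leakage-safe preprocessing: confound regression, min-max scaling, SMOTE.

All parameters are estimated on the normative (control) training set only
and then applied unchanged to held-out data.  Confound removal is per-feature
ordinary least squares on the supplied covariates (sex encoded 0/1);
residuals are re-centered at the training mean so scaled values remain
comparable across groups.  Min-max maps the training range onto [0, 1] and
is deliberately *not* clipped on unseen data: values escaping the normative
range are exactly the anomaly signal downstream detectors consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .exceptions import (
    DataError,
    DegenerateFeatureError,
    ParameterError,
    SingularCovariateError,
)
from .io import FeatureMatrix


def encode_covariates(
    demographics: pd.DataFrame,
    covariates: list[str],
    subjects: list[str],
) -> np.ndarray:
    """Build a numeric (subjects x covariates) design from demographics.

    Categorical columns with exactly two levels (e.g. sex M/F) are encoded
    as a 0/1 indicator of the lexicographically larger level.
    """
    df = demographics.set_index("ID").loc[list(subjects), covariates]
    out = np.empty((len(subjects), len(covariates)), dtype=float)
    for j, cov in enumerate(covariates):
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            out[:, j] = col.to_numpy(dtype=float)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                raise ParameterError(
                    f"covariate {cov!r} has {len(levels)} levels; only binary "
                    "categorical covariates are supported"
                )
            out[:, j] = (col.astype(str) == levels[-1]).astype(float)
    if not np.all(np.isfinite(out)):
        raise DataError(f"non-finite covariate values in {covariates}")
    return out


@dataclass
class ConfoundModel:
    """Per-feature OLS of features on covariates, fit on training controls."""

    coef: np.ndarray        # (1 + n_cov, n_features); row 0 is the intercept
    train_mean: np.ndarray  # (n_features,)
    n_covariates: int

    @classmethod
    def fit(cls, train: np.ndarray, covariates: np.ndarray | None) -> "ConfoundModel":
        train = np.asarray(train, dtype=float)
        if covariates is None or covariates.shape[1] == 0:
            # identity transform
            return cls(np.zeros((1, train.shape[1])), train.mean(axis=0), 0)
        Z = np.column_stack([np.ones(len(train)), covariates])
        if len(train) < Z.shape[1] + 1:
            raise SingularCovariateError(
                f"need >= {Z.shape[1] + 1} training subjects for "
                f"{covariates.shape[1]} covariate(s), got {len(train)}"
            )
        rank = np.linalg.matrix_rank(Z)
        if rank < Z.shape[1]:
            raise SingularCovariateError(
                "rank-deficient covariate design (collinear or constant covariate)"
            )
        coef, *_ = np.linalg.lstsq(Z, train, rcond=None)
        return cls(coef, train.mean(axis=0), covariates.shape[1])

    def residualize(self, X: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
        if self.n_covariates == 0:
            return np.asarray(X, dtype=float).copy()
        if covariates is None or covariates.shape[1] != self.n_covariates:
            raise ParameterError(
                f"model was fit with {self.n_covariates} covariate(s); "
                "matching covariates required at transform time"
            )
        Z = np.column_stack([np.ones(len(X)), covariates])
        return X - Z @ self.coef + self.train_mean


@dataclass
class MinMaxModel:
    """Per-feature affine map sending the training range onto [0, 1]."""

    min_: np.ndarray
    max_: np.ndarray

    @classmethod
    def fit(cls, train: np.ndarray, feature_names: list[str] | None = None) -> "MinMaxModel":
        train = np.asarray(train, dtype=float)
        lo, hi = train.min(axis=0), train.max(axis=0)
        degenerate = np.flatnonzero(hi <= lo)
        if degenerate.size:
            names = (
                [feature_names[i] for i in degenerate[:5]]
                if feature_names else degenerate[:5].tolist()
            )
            raise DegenerateFeatureError(
                f"constant feature(s) on training set: {names}"
            )
        return cls(lo, hi)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.min_) / (self.max_ - self.min_)


@dataclass
class PreprocessModel:
    """Confound regression followed by min-max scaling (training-set fit)."""

    confound: ConfoundModel
    minmax: MinMaxModel
    covariate_names: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        train: FeatureMatrix,
        demographics: pd.DataFrame | None = None,
        covariates: list[str] | None = None,
    ) -> "PreprocessModel":
        if train.preprocessed:
            raise ParameterError("training matrix is already preprocessed")
        covariates = covariates or []
        Z = (
            encode_covariates(demographics, covariates, train.subjects)
            if covariates else None
        )
        if not np.all(np.isfinite(train.data)):
            raise DataError("non-finite values in training matrix")
        conf = ConfoundModel.fit(train.data, Z)
        resid = conf.residualize(train.data, Z)
        names = [k.column_name() for k in train.keys]
        mm = MinMaxModel.fit(resid, names)
        return cls(conf, mm, list(covariates))

    def transform(
        self,
        m: FeatureMatrix,
        demographics: pd.DataFrame | None = None,
    ) -> FeatureMatrix:
        if m.preprocessed:
            raise ParameterError(
                "matrix is already preprocessed; refusing to scale twice"
            )
        Z = (
            encode_covariates(demographics, self.covariate_names, m.subjects)
            if self.covariate_names else None
        )
        resid = self.confound.residualize(m.data, Z)
        scaled = self.minmax.transform(resid)
        return FeatureMatrix(list(m.subjects), list(m.keys), scaled,
                             preprocessed=True)


@dataclass
class SmoteDetails:
    """Provenance of each synthetic SMOTE row: parents and mixing weight."""

    parent_a: np.ndarray  # index of the seed control
    parent_b: np.ndarray  # index of the chosen neighbour
    lam: np.ndarray       # row = (1-lam)*a + lam*b


def smote_augment(
    controls: np.ndarray | FeatureMatrix,
    factor: int,
    k: int = 5,
    seed: int | np.random.Generator = 0,
    return_details: bool = False,
):
    """Synthetic minority oversampling of the control cohort.

    Each synthetic row interpolates between a randomly chosen control and one
    of its ``k`` nearest neighbours (Euclidean), with a uniform mixing weight.
    The originals are retained, so ``factor`` extra copies worth of synthetic
    rows gives ``n * (factor + 1)`` rows in total (15 controls, factor 4 ->
    75 rows).  ``factor = 0`` is the identity.
    """
    X = controls.data if isinstance(controls, FeatureMatrix) else np.asarray(controls, float)
    n = len(X)
    if factor < 0:
        raise ParameterError(f"factor must be >= 0, got {factor}")
    if factor == 0:
        out = X.copy()
        return (out, SmoteDetails(np.empty(0, int), np.empty(0, int),
                                  np.empty(0))) if return_details else out
    if k >= n:
        raise ParameterError(f"k={k} must be < number of controls ({n})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)          # column 0 is the point itself
    n_synth = n * factor
    pa = rng.integers(0, n, size=n_synth)
    pb = idx[pa, rng.integers(1, k + 1, size=n_synth)]
    lam = rng.uniform(0.0, 1.0, size=n_synth)
    synth = X[pa] + lam[:, None] * (X[pb] - X[pa])
    out = np.vstack([X, synth])
    if return_details:
        return out, SmoteDetails(pa, pb, lam)
    return out
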