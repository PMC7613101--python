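"""Bootstrapped single-subject evaluation of normative detectors.

Cohorts of interest are heavily imbalanced (e.g. 90 controls vs 8 patients),
so detection performance is estimated by a bootstrap over train/validation
splits: in every iteration the validation set is *all* patients plus an
equal number of randomly drawn controls, the detector (and its
preprocessing) is fit on the remaining controls only, and a ROC AUC is
recorded with patients as the positive class.  Per-subject anomaly scores
are averaged over the iterations in which each subject was scored
(patients: every iteration; controls: only when held out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score

from . import detectors
from .exceptions import (
    CohortSizeError,
    InsufficientDataError,
    ParameterError,
)
from .io import FeatureMatrix, TractometryDataset, assemble_features
from .preprocess import PreprocessModel

MIN_TRAIN_CONTROLS = 8

METHODS = ("ae", "zscore", "pca")


@dataclass
class BootstrapPlan:
    """Protocol parameters for the bootstrapped evaluation."""

    n_iterations: int = 100
    seed: int = 0
    covariates: list[str] = field(default_factory=list)
    zscore_mode: str = "absolute"
    variance_threshold: float = 0.85
    ae_spec: detectors.AutoencoderSpec | None = None


@dataclass
class AnomalyResult:
    subject_id: str
    method: str
    metric: str
    score_mean: float
    score_sd: float
    n_scored: int


@dataclass
class GroupStats:
    test_name: str
    statistic: float
    pvalue: float
    cohens_d: float


@dataclass
class EvaluationReport:
    method: str
    metric: str
    iteration_aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    iteration_pr_aucs: np.ndarray
    mean_pr_auc: float
    pr_baseline: float
    group_stats: GroupStats
    clinical: tuple[float, float] | None = None


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC with positives = label 1; equals the normalized Mann-Whitney
    U statistic (ties counted half)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ParameterError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Precision-recall AUC (average precision); the random-classifier
    baseline equals the positive-class prevalence."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ParameterError("pr_auc requires both classes present")
    return float(average_precision_score(labels, np.asarray(scores, float)))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled (n-1) standard deviation, |mean difference|."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def group_stats(
    scores_controls: np.ndarray,
    scores_patients: np.ndarray,
    balanced: bool | None = None,
) -> GroupStats:
    """Compare score distributions: equal-variance two-tailed t-test when the
    groups are balanced, two-sample Kolmogorov-Smirnov otherwise; always
    reports Cohen's d."""
    a = np.asarray(scores_controls, float)
    b = np.asarray(scores_patients, float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 scores")
    if balanced is None:
        balanced = len(a) == len(b)
    if balanced:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        name = "t"
    else:
        stat, p = sps.ks_2samp(a, b)
        name = "ks"
    return GroupStats(name, float(stat), float(p), cohens_d(a, b))


def relate(
    anomaly_scores: pd.Series | np.ndarray,
    clinical: pd.Series | np.ndarray,
) -> tuple[float, float]:
    """Spearman rank correlation between anomaly and clinical scores.

    Subjects missing either value are excluded pairwise; at least 5 complete
    pairs are required.
    """
    s = pd.Series(anomaly_scores).reset_index(drop=True) \
        if not isinstance(anomaly_scores, pd.Series) else anomaly_scores
    c = pd.Series(clinical)
    if isinstance(anomaly_scores, pd.Series) and isinstance(clinical, pd.Series):
        df = pd.concat([s.rename("a"), c.rename("c")], axis=1, join="inner")
    else:
        df = pd.DataFrame({"a": np.asarray(anomaly_scores, float),
                           "c": np.asarray(clinical, float)})
    df = df.dropna()
    if len(df) < 5:
        raise InsufficientDataError(
            f"need >= 5 paired observations, got {len(df)}"
        )
    if df["c"].nunique() < 2 or df["a"].nunique() < 2:
        raise InsufficientDataError("zero variance in one of the variables")
    rho, p = sps.spearmanr(df["a"], df["c"])
    return float(rho), float(p)


def _fit_and_score(method, train_pre, val_pre, plan, it_seed):
    if method == "ae":
        spec = plan.ae_spec or detectors.AutoencoderSpec()
        spec = detectors.AutoencoderSpec(
            epochs=spec.epochs, batch_size=spec.batch_size,
            learning_rate=spec.learning_rate,
            l1_bottleneck=spec.l1_bottleneck,
            validation_split=spec.validation_split, seed=it_seed,
        )
        model = detectors.fit_autoencoder(train_pre, spec)
        return detectors.score_mae(model, val_pre)
    if method == "zscore":
        stats = detectors.NormativeStats.fit(train_pre)
        return detectors.score_zscore(stats, val_pre, mode=plan.zscore_mode)
    if method == "pca":
        model = detectors.fit_pca_mahalanobis(
            train_pre, plan.variance_threshold
        )
        return detectors.score_mahalanobis(model, val_pre)
    raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")


def run_bootstrap(
    dataset: TractometryDataset,
    demographics: pd.DataFrame,
    metric: str,
    method: str = "ae",
    plan: BootstrapPlan | None = None,
    control_label: str = "control",
    clinical_column: str | None = None,
) -> tuple[list[AnomalyResult], EvaluationReport]:
    """Run the full bootstrapped detection protocol for one metric/method."""
    plan = plan or BootstrapPlan()
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")
    fm = assemble_features(dataset, metric)
    demo = demographics.set_index("ID")
    missing = [s for s in fm.subjects if s not in demo.index]
    if missing:
        raise CohortSizeError(f"subjects missing from demographics: {missing}")
    groups = demo.loc[fm.subjects, "group"].astype(str)
    controls = [s for s in fm.subjects if groups[s] == control_label]
    patients = [s for s in fm.subjects if groups[s] != control_label]
    n_pat = len(patients)
    if n_pat < 2:
        raise CohortSizeError(f"need >= 2 patients, got {n_pat}")
    if len(controls) < n_pat + MIN_TRAIN_CONTROLS:
        raise CohortSizeError(
            f"need >= {n_pat + MIN_TRAIN_CONTROLS} controls "
            f"(patients + minimum training size), got {len(controls)}"
        )

    ss = np.random.SeedSequence(plan.seed)
    children = ss.spawn(plan.n_iterations)
    per_subject: dict[str, list[float]] = {s: [] for s in fm.subjects}
    aucs, pr_aucs = [], []
    prevalence = n_pat / (2 * n_pat)

    for child in children:
        rng = np.random.default_rng(child)
        it_seed = int(rng.integers(0, 2**31 - 1))
        val_controls = list(
            np.array(controls)[rng.choice(len(controls), n_pat, replace=False)]
        )
        train_subjects = [s for s in controls if s not in val_controls]
        val_subjects = patients + val_controls
        train_fm = fm.subset(train_subjects)
        val_fm = fm.subset(val_subjects)
        pre = PreprocessModel.fit(train_fm, demographics, plan.covariates)
        train_pre = pre.transform(train_fm, demographics)
        val_pre = pre.transform(val_fm, demographics)
        scores = _fit_and_score(method, train_pre, val_pre, plan, it_seed)
        labels = np.array([1] * n_pat + [0] * n_pat)
        aucs.append(roc_auc(scores, labels))
        pr_aucs.append(pr_auc(scores, labels))
        for s, sc in zip(val_subjects, scores):
            per_subject[s].append(float(sc))

    results = []
    for s in fm.subjects:
        vals = per_subject[s]
        if not vals:
            continue
        results.append(AnomalyResult(
            subject_id=s, method=method, metric=metric,
            score_mean=float(np.mean(vals)),
            score_sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            n_scored=len(vals),
        ))

    mean_scores = {r.subject_id: r.score_mean for r in results}
    ctrl_scores = np.array([mean_scores[s] for s in controls if s in mean_scores])
    pat_scores = np.array([mean_scores[s] for s in patients])
    gstats = group_stats(ctrl_scores, pat_scores,
                         balanced=len(ctrl_scores) == len(pat_scores))

    clinical = None
    if clinical_column is not None:
        pat_series = pd.Series(pat_scores, index=patients)
        clin = demo.loc[patients, clinical_column]
        clinical = relate(pat_series, clin)

    aucs = np.asarray(aucs)
    pr_aucs = np.asarray(pr_aucs)
    report = EvaluationReport(
        method=method, metric=metric,
        iteration_aucs=aucs, mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        iteration_pr_aucs=pr_aucs, mean_pr_auc=float(pr_aucs.mean()),
        pr_baseline=prevalence, group_stats=gstats, clinical=clinical,
    )
    return results, report
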