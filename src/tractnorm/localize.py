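"""Along-tract anomaly localization by leave-one-out reconstruction errors.

A single patient is compared against N healthy controls: the autoencoder is
trained on all N controls and the patient's signed per-feature
reconstruction error recorded; then each control in turn is left out, the
patient is shuffled back into the population, the network is retrained on
the other N-1 controls plus the patient, and the held-out control's error
recorded, yielding an N-sample empirical null per feature.  Every subject
(patient or control) is thus scored against a population of the N others,
so under the null the patient's error rank is uniform and a feature is
flagged when the patient's *positive* error exceeds every null error (an
exchangeable one-sided p <= 1/(N+1)).  To suppress isolated noise hits,
only maximal runs of at least two consecutive flagged sections within one
(bundle, hemisphere, metric) tract are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detectors import AutoencoderSpec, fit_autoencoder, reconstruction_errors
from .exceptions import AlignmentError, CohortSizeError
from .io import FeatureKey, FeatureMatrix
from .preprocess import PreprocessModel

MIN_CONTROLS = 10
MIN_RUN_LENGTH = 2


@dataclass
class AnomalyRun:
    bundle: str
    hemisphere: str | None
    metric: str | None
    start: int  # 1-based section, inclusive
    end: int    # inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sections(self) -> list[int]:
        return list(range(self.start, self.end + 1))


@dataclass
class SegmentAnomalyMap:
    """Per-feature localization table plus the reported anomaly runs."""

    table: pd.DataFrame  # metric, bundle, hemisphere, section, patient_error,
                         # null_max, flagged, run_id
    runs: list[AnomalyRun] = field(default_factory=list)

    @property
    def flagged_fraction(self) -> float:
        return float(self.table["flagged"].mean())


def _find_runs(flags: np.ndarray, sections: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive flagged sections, length >= MIN_RUN_LENGTH."""
    runs: list[tuple[int, int]] = []
    start = prev = None

    def close():
        if start is not None and prev - start + 1 >= MIN_RUN_LENGTH:
            runs.append((start, prev))

    for flag, sec in zip(flags, sections):
        if flag:
            if start is None:
                start, prev = sec, sec
            elif sec == prev + 1:
                prev = sec
            else:
                close()
                start, prev = sec, sec
        else:
            close()
            start = prev = None
    close()
    return runs


def loo_segment_anomalies(
    controls: FeatureMatrix,
    patient: np.ndarray,
    spec: AutoencoderSpec | None = None,
    demographics: pd.DataFrame | None = None,
    covariates: list[str] | None = None,
    patient_covariates: pd.DataFrame | None = None,
    two_sided: bool = False,
) -> SegmentAnomalyMap:
    """Localize a single patient's anomalies to tract sections.

    ``controls`` is the raw (unpreprocessed) control matrix; ``patient`` a
    raw feature vector aligned with ``controls.keys``.  Preprocessing
    (optional confound regression + min-max) is refit inside every
    leave-one-out fold.
    """
    spec = spec or AutoencoderSpec()
    patient = np.asarray(patient, dtype=float).ravel()
    if patient.shape[0] != controls.n:
        raise AlignmentError(
            f"patient has {patient.shape[0]} features, controls have {controls.n}"
        )
    N = len(controls.subjects)
    if N < MIN_CONTROLS:
        raise CohortSizeError(f"need >= {MIN_CONTROLS} controls, got {N}")

    covariates = covariates or []
    demo_all = None
    if covariates:
        if demographics is None or patient_covariates is None:
            raise AlignmentError(
                "confound correction requires demographics for controls and patient"
            )
        demo_all = pd.concat([demographics, patient_covariates], ignore_index=True)

    # every fold trains from the same seed (same initialization and batch
    # schedule): the only thing that differs between folds is which subject
    # is held out, so model-initialization variance cancels from the
    # empirical null instead of inflating it
    seeds = [spec.seed] * (N + 1)

    def _error_of(train_fm: FeatureMatrix, test_vec: np.ndarray,
                  test_subject: str, seed: int) -> np.ndarray:
        pre = PreprocessModel.fit(train_fm, demo_all, covariates)
        train_pre = pre.transform(train_fm, demo_all)
        test_fm = FeatureMatrix([test_subject], list(controls.keys),
                                test_vec[None, :])
        test_pre = pre.transform(test_fm, demo_all)
        fold_spec = AutoencoderSpec(
            epochs=spec.epochs, batch_size=spec.batch_size,
            learning_rate=spec.learning_rate,
            l1_bottleneck=spec.l1_bottleneck,
            validation_split=spec.validation_split, seed=seed,
        )
        model = fit_autoencoder(train_pre, fold_spec)
        return reconstruction_errors(model, test_pre)[0]

    patient_id = "__patient__"
    if covariates and patient_covariates is not None:
        patient_id = str(patient_covariates["ID"].iloc[0])

    # (a) patient vs all N controls
    e_patient = _error_of(controls, patient, patient_id, seeds[0])

    # (b) leave-one-out null: each held-out control vs the other N-1
    #     controls with the patient shuffled back into the population
    null = np.empty((N, controls.n))
    for c in range(N):
        keep = [s for i, s in enumerate(controls.subjects) if i != c]
        train_data = np.vstack([controls.subset(keep).data, patient[None, :]])
        train_fm = FeatureMatrix(keep + [patient_id], list(controls.keys),
                                 train_data)
        null[c] = _error_of(train_fm, controls.data[c],
                            controls.subjects[c], seeds[c + 1])

    # (c) flag features where the patient exceeds the entire null
    if two_sided:
        flagged = np.abs(e_patient) > np.abs(null).max(axis=0)
        null_max = np.abs(null).max(axis=0)
    else:
        null_max = null.max(axis=0)
        flagged = (e_patient > 0) & (e_patient > null_max)

    rows = []
    for i, key in enumerate(controls.keys):
        rows.append({
            "metric": key.metric, "bundle": key.bundle,
            "hemisphere": key.hemisphere or "", "section": key.section,
            "patient_error": e_patient[i], "null_max": null_max[i],
            "flagged": bool(flagged[i]), "run_id": -1,
        })
    table = pd.DataFrame(rows).sort_values(
        ["metric", "bundle", "hemisphere", "section"], na_position="first",
    ).reset_index(drop=True)

    # (d) maximal runs of >= 2 consecutive flagged sections per tract
    runs: list[AnomalyRun] = []
    for (metric, bundle, hemi), grp in table.groupby(
        ["metric", "bundle", "hemisphere"], dropna=False
    ):
        grp = grp.sort_values("section")
        for start, end in _find_runs(grp["flagged"].to_numpy(),
                                     grp["section"].to_numpy()):
            run = AnomalyRun(bundle, hemi or None, metric, int(start), int(end))
            run_id = len(runs)
            runs.append(run)
            sel = (
                (table["bundle"] == bundle)
                & (table["hemisphere"] == (hemi or ""))
                & table["section"].between(start, end)
            )
            if metric is None or (isinstance(metric, float) and np.isnan(metric)):
                sel &= table["metric"].isna()
            else:
                sel &= table["metric"] == metric
            table.loc[sel, "run_id"] = run_id

    return SegmentAnomalyMap(table=table, runs=runs)
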