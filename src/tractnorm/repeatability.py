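"""Test-retest reliability: intraclass correlation, CoV, ICC projection.

ICC forms follow the two-way mixed-effects mean-square decomposition with
rows = subjects (n) and columns = sessions (k):

* ``C_1`` — consistency of single measurements:
  ``(MS_R - MS_E) / (MS_R + (k-1) MS_E)``
* ``A_k`` — absolute agreement of session-averaged measurements:
  ``(MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n)``

Confidence intervals use the standard F-based construction (exact for C_1;
Satterthwaite degrees of freedom for the absolute-agreement form, with the
single-measure bounds stepped up by Spearman-Brown for A_k).

``project_icc`` transfers a reliability estimate between cohorts by
assuming the measurement-error variance carries over: with
``var_e = (1 - ICC_src) * sd_src^2 * inflation``, the projected ICC is
``1 - var_e / sd_target^2`` (clipped to [0, 1]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError, InsufficientDataError, ParameterError


@dataclass
class RepeatedMeasures:
    """Complete subjects x sessions matrix of one scalar measure."""

    values: np.ndarray
    subjects: list[str] | None = None
    sessions: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be 2-D (subjects x sessions)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise InsufficientDataError(
                f"need >= 2 subjects and >= 2 sessions, got {n} x {k}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("missing or non-finite cells in repeated measures")
        if self.subjects is None:
            self.subjects = [f"sub-{i+1}" for i in range(n)]
        if self.sessions is None:
            self.sessions = [f"ses-{j+1}" for j in range(k)]

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject: str = "subject",
                  session: str = "session", value: str = "value") -> "RepeatedMeasures":
        wide = df.pivot(index=subject, columns=session, values=value)
        if wide.isna().any().any():
            raise DataError("incomplete subject x session table")
        return cls(wide.to_numpy(), [str(s) for s in wide.index],
                   [str(s) for s in wide.columns])


def _mean_squares(values: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum(
        (values - row_means[:, None] - col_means[None, :] + grand) ** 2
    )
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e, n, k


def icc(
    data: RepeatedMeasures,
    form: str = "C_1",
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Two-way mixed ICC with a (1 - alpha) F-based confidence interval.

    ``form='C_1'``: consistency, single measurements. ``form='A_k'``:
    absolute agreement, average measurements.  Degenerate data with zero
    between-subject variance returns estimate 0 with a warning.
    """
    if form not in ("C_1", "A_k"):
        raise ParameterError(f"form must be 'C_1' or 'A_k', got {form!r}")
    ms_r, ms_c, ms_e, n, k = _mean_squares(data.values)
    row_var = np.var(data.values.mean(axis=1))
    if row_var == 0 or ms_r == 0:
        warnings.warn("zero between-subject variance; ICC set to 0")
        return 0.0, (0.0, 0.0)

    if form == "C_1":
        est = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
        if ms_e == 0:
            return float(est), (float(est), float(est))
        f_obs = ms_r / ms_e
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(est), (float(lo), float(hi))

    # A_k
    est = (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n)
    # single-measure absolute-agreement bounds (Satterthwaite dof), then
    # Spearman-Brown step-up to average measurements
    r1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))
    if ms_e == 0 and ms_c == ms_e:
        return float(est), (float(est), float(est))
    a = k * r1 / (n * (1 - r1)) if r1 < 1 else np.inf
    b = 1 + k * r1 * (n - 1) / (n * (1 - r1)) if r1 < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return float(est), (float(est), float(est))
    num = (a * ms_c + b * ms_e) ** 2
    den = (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_star_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_star_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (ms_r - f_star_l * ms_e) / (
        f_star_l * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r
    )
    hi1 = n * (f_star_u * ms_r - ms_e) / (
        k * ms_c + (k * n - k - n) * ms_e + n * f_star_u * ms_r
    )
    lo = k * lo1 / (1 + (k - 1) * lo1)
    hi = k * hi1 / (1 + (k - 1) * hi1)
    return float(est), (float(lo), float(hi))


def cov_repeatability(data: RepeatedMeasures) -> float:
    """Coefficient of variation: within-subject sd over subject mean,
    averaged across subjects."""
    means = data.values.mean(axis=1)
    if np.any(means <= 0):
        raise DataError("CoV undefined: a subject mean is <= 0")
    sds = data.values.std(axis=1, ddof=1)
    return float(np.mean(sds / means))


def project_icc(
    icc_source: float,
    sd_source: float,
    sd_target: float,
    error_inflation: float = 1.0,
) -> float:
    """Project a source-cohort ICC onto a target cohort, assuming the
    measurement-error variance transfers (optionally inflated)."""
    if not 0 < icc_source < 1:
        raise ParameterError(f"icc_source must be in (0,1), got {icc_source}")
    if sd_source <= 0 or sd_target <= 0:
        raise ParameterError("standard deviations must be > 0")
    if error_inflation <= 0:
        raise ParameterError("error_inflation must be > 0")
    var_e = (1.0 - icc_source) * sd_source**2 * error_inflation
    if var_e >= sd_target**2:
        warnings.warn(
            "projected error variance exceeds target variance; ICC set to 0"
        )
        return 0.0
    return float(np.clip(1.0 - var_e / sd_target**2, 0.0, 1.0))
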