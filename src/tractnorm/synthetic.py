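"""Seeded synthetic tractometry cohorts with ground-truth anomalies.

Generates cohorts in the exact input formats consumed by the rest of the
package: a demographics table (ID, group, age, sex, clinical) and a
tractometry dataset (one metric per sheet, ``bundle_hemi_section`` columns,
20 sections per bundle by default).

The generative model for one feature value is

    value = mean_curve(bundle, metric, section)
          + age_slope * (age - midpoint) + sex_offset * sex
          + subject_offset                       (per subject x tract x metric)
          + along-tract noise                    (squared-exponential kernel)
          + session noise                        (iid, test-retest designs)
          + anomaly bump                         (designated patients only)

Mean curves are low-order cosine expansions, so profiles are smooth the way
real along-tract profiles are.  Anomalies are half-cosine bumps of given
amplitude (in units of the total per-feature sd), width >= 2 sections, so
localization with +-1-section tolerance is meaningful.  Generation is a pure
function of the spec (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import TractometryDataset, write_tractometry


@dataclass(frozen=True)
class AnomalySpec:
    """One injected lesion: a half-cosine bump on a tract profile."""

    bundle: str
    hemisphere: str | None
    metric: str
    start: int           # 1-based section, inclusive
    width: int           # >= 2 sections
    amplitude: float     # in units of the total per-feature sd
    fraction_affected: float = 1.0


@dataclass
class CohortSpec:
    n_controls: int = 60
    n_patients: int = 8
    bundles: tuple = (("AF", "left"), ("AF", "right"), ("CC4", None))
    n_sections: int = 20
    metrics: tuple = ("RISH0",)
    between_subject_sd: float = 0.04
    noise_sd: float = 0.04
    length_scale: float = 3.0    # sections, squared-exponential kernel
    age_slope: float = 0.002     # per year, applied to every feature
    sex_offset: float = 0.01
    age_range: tuple = (8.0, 18.0)
    sessions: int = 1
    session_sd: float = 0.0
    anomalies: tuple = ()
    clinical_noise_sd: float = 5.0
    clinical_slope: float = 5.0  # clinical score per unit injected amplitude
    seed: int = 0

    @property
    def sigma_total(self) -> float:
        """Total per-feature sd (subject + along-tract noise); the unit in
        which anomaly amplitudes are expressed."""
        return float(np.hypot(self.between_subject_sd, self.noise_sd))


@dataclass
class GeneratedCohort:
    datasets: list          # one TractometryDataset per session
    demographics: pd.DataFrame
    ground_truth: list      # dicts: subject, bundle, hemisphere, metric,
                            # start, end, amplitude

    @property
    def dataset(self) -> TractometryDataset:
        return self.datasets[0]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.demographics.to_csv(out / "demographics.csv", index=False)
        for r, ds in enumerate(self.datasets, start=1):
            name = "tractometry.xlsx" if len(self.datasets) == 1 \
                else f"tractometry_ses-{r}.xlsx"
            write_tractometry(ds, out / name)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2)


def half_cosine_bump(width: int) -> np.ndarray:
    """Unit-peak half-cosine profile over ``width`` sections (peak exactly 1
    at the center section when ``width`` is odd)."""
    u = (np.arange(width) + 0.5) / width
    return np.sin(np.pi * u)


def inject_anomaly(
    profile: np.ndarray,
    start: int,
    width: int,
    amplitude: float,
    sigma: float,
) -> np.ndarray:
    """Add an ``amplitude * sigma`` half-cosine bump over sections
    [start, start+width-1] (1-based) of a single tract profile."""
    profile = np.asarray(profile, dtype=float)
    S = profile.shape[0]
    if width < 1:
        raise ParameterError(f"width must be >= 1, got {width}")
    if start < 1 or start + width - 1 > S:
        raise ParameterError(
            f"bump [{start}, {start + width - 1}] outside sections 1..{S}"
        )
    out = profile.copy()
    out[start - 1:start - 1 + width] += amplitude * sigma * half_cosine_bump(width)
    return out


def _se_cholesky(S: int, length_scale: float) -> np.ndarray:
    idx = np.arange(S)
    K = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2 * length_scale**2))
    return np.linalg.cholesky(K + 1e-10 * np.eye(S))


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Generate a full cohort (plus ground truth) from a spec; deterministic
    for a fixed ``spec.seed``."""
    S = spec.n_sections
    tracts = [(b, h) for b, h in spec.bundles]
    for a in spec.anomalies:
        if (a.bundle, a.hemisphere) not in tracts:
            raise ParameterError(f"anomaly tract {(a.bundle, a.hemisphere)} "
                                 f"not in bundles {tracts}")
        if a.metric not in spec.metrics:
            raise ParameterError(f"anomaly metric {a.metric!r} not in {spec.metrics}")
        if a.width < 1 or a.start < 1 or a.start + a.width - 1 > S:
            raise ParameterError(
                f"anomaly [{a.start}, {a.start + a.width - 1}] outside 1..{S}"
            )
        if not np.isfinite(a.amplitude):
            raise ParameterError("anomaly amplitude must be finite")
    if spec.between_subject_sd <= 0 or spec.noise_sd <= 0:
        raise ParameterError("sds must be > 0")
    if spec.sessions < 1:
        raise ParameterError("sessions must be >= 1")

    ss = np.random.SeedSequence(spec.seed)
    r_coef, r_demo, r_subj, r_noise, r_sess, r_anom, r_clin = (
        np.random.default_rng(c) for c in ss.spawn(7)
    )

    n_total = spec.n_controls + spec.n_patients
    ids = [f"ctrl-{i+1:03d}" for i in range(spec.n_controls)] + \
          [f"pat-{i+1:03d}" for i in range(spec.n_patients)]
    groups = ["control"] * spec.n_controls + ["patient"] * spec.n_patients

    ages = r_demo.uniform(*spec.age_range, size=n_total)
    sexes = r_demo.integers(0, 2, size=n_total)  # 0 = F, 1 = M
    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])

    # smooth population mean curves per (tract, metric)
    mean_curves: dict[tuple, np.ndarray] = {}
    t = (np.arange(S) + 0.5) / S
    for metric in spec.metrics:
        for bundle, hemi in tracts:
            c0 = r_coef.uniform(0.45, 0.65)
            cq = r_coef.normal(0.0, 0.03, size=3)
            curve = c0 + sum(
                cq[q] * np.cos((q + 1) * np.pi * t) for q in range(3)
            )
            mean_curves[(bundle, hemi, metric)] = curve

    chol = _se_cholesky(S, spec.length_scale)
    sigma = spec.sigma_total

    # assign which patients carry each anomaly
    ground_truth: list[dict] = []
    bumps: dict[tuple, np.ndarray] = {}  # (subj_idx, bundle, hemi, metric) -> bump
    for a in spec.anomalies:
        n_aff = int(np.ceil(a.fraction_affected * spec.n_patients))
        affected = r_anom.choice(spec.n_patients, size=n_aff, replace=False)
        shape = a.amplitude * sigma * half_cosine_bump(a.width)
        for pi in sorted(affected):
            subj = spec.n_controls + pi
            key = (subj, a.bundle, a.hemisphere, a.metric)
            bump = bumps.get(key, np.zeros(S)).copy()
            bump[a.start - 1:a.start - 1 + a.width] += shape
            bumps[key] = bump
            ground_truth.append({
                "subject": ids[subj], "bundle": a.bundle,
                "hemisphere": a.hemisphere, "metric": a.metric,
                "start": a.start, "end": a.start + a.width - 1,
                "amplitude": a.amplitude,
            })

    # subject-level stable components (shared across sessions)
    base: dict[str, np.ndarray] = {}
    for metric in spec.metrics:
        arr = np.empty((n_total, len(tracts) * S))
        for ti, (bundle, hemi) in enumerate(tracts):
            curve = mean_curves[(bundle, hemi, metric)]
            offs = r_subj.normal(0.0, spec.between_subject_sd, size=n_total)
            noise = (chol @ r_noise.normal(
                0.0, spec.noise_sd, size=(S, n_total))).T
            block = curve[None, :] + offs[:, None] + noise
            block += (spec.age_slope * (ages - mid_age)
                      + spec.sex_offset * sexes)[:, None]
            for j in range(n_total):
                bump = bumps.get((j, bundle, hemi, metric))
                if bump is not None:
                    block[j] += bump
            arr[:, ti * S:(ti + 1) * S] = block
        base[metric] = arr

    columns = []
    for bundle, hemi in tracts:
        for s in range(1, S + 1):
            columns.append(f"{bundle}_{hemi}_{s}" if hemi else f"{bundle}_{s}")

    datasets = []
    for _r in range(spec.sessions):
        frames = {}
        for metric in spec.metrics:
            vals = base[metric]
            if spec.sessions > 1 and spec.session_sd > 0:
                vals = vals + r_sess.normal(0.0, spec.session_sd,
                                            size=vals.shape)
            df = pd.DataFrame(vals, index=pd.Index(ids, name="ID"),
                              columns=columns)
            frames[metric] = df
        datasets.append(TractometryDataset(frames))

    # clinical score: baseline noise plus severity (total injected amplitude)
    severity = np.zeros(n_total)
    for gt in ground_truth:
        severity[ids.index(gt["subject"])] += gt["amplitude"]
    clinical = (50.0 + spec.clinical_slope * severity
                + r_clin.normal(0.0, spec.clinical_noise_sd, size=n_total))

    demographics = pd.DataFrame({
        "ID": ids, "group": groups,
        "age": np.round(ages, 2),
        "sex": np.where(sexes == 1, "M", "F"),
        "clinical": np.round(clinical, 3),
    })
    return GeneratedCohort(datasets, demographics, ground_truth)


def spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a plain JSON-style dict (CLI config)."""
    d = dict(d)
    if "bundles" in d:
        d["bundles"] = tuple(
            (b[0], b[1] if len(b) > 1 and b[1] else None) for b in d["bundles"]
        )
    if "anomalies" in d:
        d["anomalies"] = tuple(AnomalySpec(**a) for a in d["anomalies"])
    if "metrics" in d:
        d["metrics"] = tuple(d["metrics"])
    if "age_range" in d:
        d["age_range"] = tuple(d["age_range"])
    return CohortSpec(**d)
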