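"""Reading and writing tractometry workbooks and demographics tables.

The tractometry container is an ``.xlsx`` workbook with one sheet per
microstructural metric (FA, MD, RISH0, ...).  Each sheet has one row per
subject; the first column is the subject ID and the remaining columns are
named ``bundle_hemi_section``, where ``hemi`` is ``left``/``right`` (omitted
for commissural bundles) and ``section`` is the 1-based along-tract sampling
index.  A directory of ``<metric>.csv`` files with the same layout is
accepted as a plain-text alternative.

Demographics are a CSV with required columns ``ID`` and ``group`` plus
optional covariates (age, sex) and clinical scores.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    ConsistencyError,
    FormatError,
    LookupError_,
)

logger = logging.getLogger(__name__)

_HEMISPHERES = ("left", "right")


@dataclass(frozen=True, order=True)
class FeatureKey:
    """Identity of one tractometry feature: (metric, bundle, hemisphere, section).

    ``hemisphere`` is ``None`` for commissural bundles. ``section`` is 1-based.
    ``metric`` may be ``None`` when a key is parsed from a column name alone
    (sheets carry the metric).
    """

    metric: str | None
    bundle: str
    hemisphere: str | None
    section: int

    def __post_init__(self):
        if self.section < 1:
            raise FormatError(f"section must be >= 1, got {self.section}")
        if self.hemisphere not in (None, "left", "right"):
            raise FormatError(f"invalid hemisphere {self.hemisphere!r}")

    @property
    def tract(self) -> tuple[str, str | None]:
        return (self.bundle, self.hemisphere)

    def column_name(self) -> str:
        if self.hemisphere is None:
            return f"{self.bundle}_{self.section}"
        return f"{self.bundle}_{self.hemisphere}_{self.section}"

    def with_metric(self, metric: str) -> "FeatureKey":
        return FeatureKey(metric, self.bundle, self.hemisphere, self.section)

    def _sort_key(self):
        return (self.metric or "", self.bundle, self.hemisphere or "", self.section)


def parse_feature_key(column_name: str, metric: str | None = None) -> FeatureKey:
    """Parse a ``bundle_hemi_section`` column name.

    Bundle names may themselves contain underscores (``SLF_II``), so parsing
    is right-to-left: the last token must be the integer section, the
    second-to-last is the hemisphere iff it equals ``left``/``right``
    (case-insensitive), and everything before is the bundle.
    """
    if not column_name or not column_name.strip():
        raise FormatError("empty column name")
    tokens = column_name.strip().split("_")
    if len(tokens) < 2 or not re.fullmatch(r"\d+", tokens[-1]):
        raise FormatError(
            f"column {column_name!r} does not end in '_<section>'"
        )
    section = int(tokens[-1])
    if section < 1:
        raise FormatError(f"column {column_name!r}: section must be >= 1")
    hemisphere = None
    bundle_tokens = tokens[:-1]
    if len(bundle_tokens) >= 2 and bundle_tokens[-1].lower() in _HEMISPHERES:
        hemisphere = bundle_tokens[-1].lower()
        bundle_tokens = bundle_tokens[:-1]
    if not bundle_tokens or any(t == "" for t in bundle_tokens):
        raise FormatError(f"column {column_name!r}: empty bundle name")
    return FeatureKey(metric, "_".join(bundle_tokens), hemisphere, section)


@dataclass
class TractometryDataset:
    """Subjects x (metric, bundle, hemisphere, section) value store.

    ``frames`` maps metric name -> DataFrame indexed by subject ID whose
    columns are the original ``bundle_hemi_section`` names.  Invariants
    (identical subject sets across metrics, contiguous 1..S sections within
    each tract) are enforced at construction.
    """

    frames: dict[str, pd.DataFrame]

    def __post_init__(self):
        if not self.frames:
            raise ConsistencyError("dataset has no metric sheets")
        ref_metric = next(iter(self.frames))
        ref_subjects = list(self.frames[ref_metric].index)
        for metric, df in self.frames.items():
            if sorted(df.index) != sorted(ref_subjects):
                extra = set(df.index) ^ set(ref_subjects)
                raise ConsistencyError(
                    f"metric {metric!r} subject set differs from "
                    f"{ref_metric!r}; offending subjects: {sorted(extra)}"
                )
            if df.index.duplicated().any():
                dups = df.index[df.index.duplicated()].tolist()
                raise ConsistencyError(f"duplicate subject IDs {dups} in {metric!r}")
        for metric in self.frames:
            self._check_contiguity(metric)

    def _check_contiguity(self, metric: str) -> None:
        by_tract: dict[tuple, list[int]] = {}
        for col in self.frames[metric].columns:
            key = parse_feature_key(str(col), metric)
            by_tract.setdefault(key.tract, []).append(key.section)
        for tract, sections in by_tract.items():
            s = sorted(sections)
            if s != list(range(1, len(s) + 1)):
                raise ConsistencyError(
                    f"metric {metric!r}, tract {tract}: sections {s} are not "
                    f"the contiguous range 1..{len(s)}"
                )

    @property
    def metrics(self) -> list[str]:
        return list(self.frames)

    @property
    def subjects(self) -> list[str]:
        return list(self.frames[self.metrics[0]].index)

    def keys_for(self, metric: str) -> list[FeatureKey]:
        if metric not in self.frames:
            raise LookupError_(f"metric {metric!r} not in dataset {self.metrics}")
        keys = [parse_feature_key(str(c), metric) for c in self.frames[metric].columns]
        return sorted(keys, key=FeatureKey._sort_key)


@dataclass
class FeatureMatrix:
    """Dense subjects x features matrix with aligned feature keys."""

    subjects: list[str]
    keys: list[FeatureKey]
    data: np.ndarray
    preprocessed: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.subjects), len(self.keys)):
            raise AlignmentError(
                f"data shape {self.data.shape} != "
                f"({len(self.subjects)}, {len(self.keys)})"
            )

    @property
    def n(self) -> int:
        return len(self.keys)

    def subset(self, subjects: Sequence[str]) -> "FeatureMatrix":
        idx = [self.subjects.index(s) for s in subjects]
        return FeatureMatrix(list(subjects), self.keys, self.data[idx],
                             self.preprocessed)

    def row(self, subject: str) -> np.ndarray:
        return self.data[self.subjects.index(subject)]


def assemble_features(dataset: TractometryDataset, metric: str) -> FeatureMatrix:
    """Concatenate one metric's tract profiles into a feature matrix.

    Columns are ordered deterministically (metric, bundle, hemisphere,
    section).  Subjects with any missing value are dropped with a logged
    warning rather than imputed.
    """
    if metric not in dataset.frames:
        raise LookupError_(f"metric {metric!r} not in dataset {dataset.metrics}")
    df = dataset.frames[metric]
    keys = dataset.keys_for(metric)
    cols = [k.column_name() for k in keys]
    sub = df[cols].astype(float)
    missing = sub.isna().any(axis=1)
    if missing.any():
        dropped = sub.index[missing].tolist()
        logger.warning(
            "assemble_features(%s): dropping %d subject(s) with missing "
            "values: %s", metric, len(dropped), dropped,
        )
        sub = sub.loc[~missing]
    return FeatureMatrix(list(sub.index), keys, sub.to_numpy())


def _frame_from_raw(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    df = df.copy()
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    df = df.set_index(id_col)
    df.index.name = "ID"
    for col in df.columns:
        parse_feature_key(str(col))  # raises FormatError with the column name
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"{origin}: non-numeric value at row {row!r}, column {col!r}"
            )
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_tractometry(path: str | Path) -> TractometryDataset:
    """Read a tractometry container.

    ``path`` may be an ``.xlsx`` workbook (one sheet per metric) or a
    directory of ``<metric>.csv`` files.
    """
    path = Path(path)
    frames: dict[str, pd.DataFrame] = {}
    if path.is_dir():
        csvs = sorted(path.glob("*.csv"))
        if not csvs:
            raise FormatError(f"no CSV files in directory {path}")
        for f in csvs:
            raw = pd.read_csv(f, float_precision="round_trip")
            frames[f.stem] = _frame_from_raw(raw, str(f))
    else:
        raw = pd.read_excel(path, sheet_name=None)
        for sheet, df in raw.items():
            frames[str(sheet)] = _frame_from_raw(df, f"{path}:{sheet}")
    return TractometryDataset(frames)


def write_tractometry(dataset: TractometryDataset, path: str | Path) -> None:
    """Write a dataset to ``.xlsx`` (file path) or CSVs (directory path)."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path) as xl:
            for metric, df in dataset.frames.items():
                # xlsx cells round-trip to 16 significant digits (<= 1 ulp);
                # the CSV container is bit-exact
                df.reset_index().to_excel(xl, sheet_name=metric, index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for metric, df in dataset.frames.items():
            # shortest round-trip float repr: values survive bit-exactly
            df.reset_index().to_csv(path / f"{metric}.csv", index=False,
                                    float_format=lambda x: repr(float(x)))


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Read the demographics CSV; requires columns ``ID`` and ``group``."""
    df = pd.read_csv(path)
    for col in ("ID", "group"):
        if col not in df.columns:
            raise FormatError(
                f"demographics file {path} is missing required column "
                f"{col!r}; found {list(df.columns)}"
            )
    df["ID"] = df["ID"].astype(str)
    if df["ID"].duplicated().any():
        dups = df.loc[df["ID"].duplicated(), "ID"].tolist()
        raise ConsistencyError(f"duplicate subject IDs in demographics: {dups}")
    return df
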