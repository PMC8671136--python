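"""Connectivity feature extraction for ROI-averaged BOLD time series.

Each subject contributes a matrix of T time points x R regions of interest
(ROIs).  The pipeline is the standard one for resting-state functional
connectivity (RSFC) classification:

1. Pearson correlation matrix (R x R) across ROIs,
2. Fisher z-transform (atanh) to variance-stabilize the correlations,
3. strictly-lower-triangular vectorization, giving R(R-1)/2 features
   (5,995 for the 110-region Harvard-Oxford parcellation).

Subjects whose connectivity contains non-finite values (e.g. a flat ROI
signal) are screened out, and per-feature standardization is always fitted
on training data only.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "FeatureVector",
    "StandardizerStats",
    "ScreeningLog",
    "read_roi_timeseries",
    "read_phenotype",
    "correlation_matrix",
    "fisher_z",
    "lower_triangle_vector",
    "features_from_record",
    "extract_features",
    "screen_subjects",
    "fit_standardizer",
    "apply_standardizer",
    "stack_features",
    "write_feature_csv",
    "read_feature_csv",
]

#: clip applied to |r| before atanh so degenerate correlations stay finite
FISHER_CLIP = 1e-7

PHENOTYPE_COLUMNS = ("SUB_ID", "SITE_ID", "DX_GROUP")


@dataclass
class SubjectRecord:
    """One subject: identifiers, diagnosis label and ROI time-series matrix.

    ``label`` uses the convention 1 = case (ASD), 0 = control (TC).
    """

    subject_id: str
    site_id: str
    label: int
    timeseries: np.ndarray
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        if self.timeseries.ndim != 2:
            raise ValueError(f"timeseries must be 2-D, got {self.timeseries.ndim}-D")
        t, r = self.timeseries.shape
        if t < 2 or r < 2:
            raise ValueError(f"timeseries needs >=2 time points and >=2 ROIs, got {t}x{r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class FeatureVector:
    """Fisher-z lower-triangle connectivity features for one subject."""

    subject_id: str
    site_id: str
    label: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class StandardizerStats:
    """Per-feature mean/sd fitted on a training set.

    Features that are constant in the training data (sd == 0) are flagged and
    mapped to 0 by :func:`apply_standardizer`.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sd = np.where(self.constant, 1.0, self.sd)
        return (x - self.mean) / sd


@dataclass
class ScreeningLog:
    excluded_subjects: list[tuple[str, str]] = field(default_factory=list)
    excluded_sites: list[tuple[str, int]] = field(default_factory=list)


def _line_iter(source) -> Iterable[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r") as fh:
            yield from fh
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        yield from source
    else:  # already an iterable of lines
        yield from source


def read_roi_timeseries(source) -> tuple[np.ndarray, list[str] | None]:
    """Parse a whitespace-delimited ROI time-series file (AFNI ``.1D`` dialect).

    Lines starting with ``#`` are header/comment lines; if the first such line
    tokenizes to as many names as there are data columns, those tokens are
    returned as ROI names.

    Returns ``(matrix, roi_names)`` where ``matrix`` is T x R and
    ``roi_names`` may be None.
    """
    rows: list[list[float]] = []
    header_tokens: list[str] | None = None
    ncols: int | None = None
    for lineno, raw in enumerate(_line_iter(source), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if header_tokens is None:
                toks = line.lstrip("#").split()
                if toks:
                    header_tokens = toks
            continue
        tokens = line.split()
        if ncols is None:
            ncols = len(tokens)
        elif len(tokens) != ncols:
            raise ValueError(
                f"ragged row at line {lineno}: expected {ncols} columns, got {len(tokens)}"
            )
        values = []
        for col, tok in enumerate(tokens, start=1):
            try:
                values.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"non-numeric token {tok!r} at line {lineno}, column {col}"
                ) from None
        rows.append(values)
    if not rows:
        raise ValueError("empty time-series file: no data rows found")
    matrix = np.asarray(rows, dtype=float)
    names = header_tokens if header_tokens and len(header_tokens) == matrix.shape[1] else None
    return matrix, names


def read_phenotype(
    source,
    dialect: str = "abide",
    columns: Sequence[str] = PHENOTYPE_COLUMNS,
) -> list[SubjectRecord]:
    """Read a phenotype CSV into subject stubs (empty 2x2 placeholder series).

    ``dialect`` selects the diagnosis coding: ``"abide"`` maps {1 -> 1 (ASD),
    2 -> 0 (TC)}; ``"native"`` expects {1, 0} directly.  Unknown codes,
    duplicate subject IDs and missing columns are rejected.
    """
    sub_col, site_col, dx_col = columns
    df = pd.read_csv(source)
    missing = [c for c in (sub_col, site_col, dx_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"phenotype table is missing required column(s) {missing}; "
            f"required: {list(columns)}"
        )
    if df[sub_col].duplicated().any():
        dupes = df.loc[df[sub_col].duplicated(), sub_col].tolist()
        raise ValueError(f"duplicate subject IDs in phenotype table: {dupes}")
    if dialect == "abide":
        mapping = {1: 1, 2: 0}
    elif dialect == "native":
        mapping = {1: 1, 0: 0}
    else:
        raise ValueError(f"unknown phenotype dialect {dialect!r}")
    stubs = []
    placeholder = np.zeros((2, 2))
    for _, row in df.iterrows():
        code = int(row[dx_col])
        if code not in mapping:
            raise ValueError(
                f"unknown diagnosis code {code} for subject {row[sub_col]!r} "
                f"under dialect {dialect!r}"
            )
        stubs.append(
            SubjectRecord(
                subject_id=str(row[sub_col]),
                site_id=str(row[site_col]),
                label=mapping[code],
                timeseries=placeholder,
            )
        )
    return stubs


def correlation_matrix(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix (R x R) of a T x R time-series matrix.

    Constant columns produce NaN rows/columns, which are deliberately
    propagated so that screening can flag the subject.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("timeseries must be a T x R matrix with T >= 2")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ts, rowvar=False)
    # corrcoef can exceed |1| by float error; NaNs stay NaN through clip
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, np.where(np.isnan(np.diag(corr)), np.nan, 1.0))
    return corr


def fisher_z(r):
    """Fisher z-transform, atanh(r), with |r| clipped to 1 - 1e-7.

    Accepts scalars or arrays. |r| > 1 (beyond float tolerance) is a domain
    error; NaNs pass through for downstream screening.
    """
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = np.abs(arr) > 1.0 + 1e-12
    if np.any(bad):
        raise ValueError("correlation magnitude exceeds 1; not a valid Pearson r")
    clipped = np.clip(arr, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP)
    out = np.arctanh(clipped)
    out = np.where(np.isnan(arr), np.nan, out)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(out)
    return out


def lower_triangle_vector(matrix: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangular entries in row-major (i, j < i) order."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def features_from_record(record: SubjectRecord) -> FeatureVector:
    """correlation -> fisher_z -> lower-triangle for one subject."""
    corr = correlation_matrix(record.timeseries)
    z = fisher_z(corr)
    return FeatureVector(
        subject_id=record.subject_id,
        site_id=record.site_id,
        label=record.label,
        values=lower_triangle_vector(z),
    )


def extract_features(records: Sequence[SubjectRecord]) -> list[FeatureVector]:
    return [features_from_record(r) for r in records]


def screen_subjects(
    records: Sequence[SubjectRecord],
    min_site_size: int = 2,
) -> tuple[list[SubjectRecord], ScreeningLog]:
    """Drop subjects with non-finite connectivity; log under-sized sites.

    Sites whose kept count falls below ``min_site_size`` remain in the
    returned records (their subjects can still inform modeling) but are logged
    as ineligible to serve as a held-out test site.
    """
    log = ScreeningLog()
    kept: list[SubjectRecord] = []
    for rec in records:
        feats = features_from_record(rec)
        if not np.all(np.isfinite(feats.values)):
            log.excluded_subjects.append((rec.subject_id, "non-finite connectivity"))
        else:
            kept.append(rec)
    if not kept:
        raise ValueError("screening excluded every subject")
    counts: dict[str, int] = {}
    for rec in kept:
        counts[rec.site_id] = counts.get(rec.site_id, 0) + 1
    for site, n in sorted(counts.items()):
        if n < min_site_size:
            log.excluded_sites.append((site, n))
    return kept, log


def fit_standardizer(train) -> StandardizerStats:
    """Fit per-feature mean and sd on training data (>= 2 vectors)."""
    x = _as_matrix(train)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to fit a standardizer")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    return StandardizerStats(mean=mean, sd=sd, constant=sd == 0.0)


def apply_standardizer(stats: StandardizerStats, data):
    """Standardize with training-set statistics; constant features map to 0.

    Accepts either a 2-D array (returns an array) or a list of
    :class:`FeatureVector` (returns new FeatureVectors).
    """
    if isinstance(data, np.ndarray):
        return stats.transform(data)
    return [
        FeatureVector(f.subject_id, f.site_id, f.label, stats.transform(f.values))
        for f in data
    ]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, np.ndarray):
        return np.atleast_2d(np.asarray(data, dtype=float))
    return np.vstack([np.asarray(f.values, dtype=float) for f in data])


def stack_features(features: Sequence[FeatureVector]):
    """Return (X, y, sites, ids) arrays for a list of feature vectors."""
    x = np.vstack([f.values for f in features])
    y = np.array([f.label for f in features], dtype=int)
    sites = np.array([f.site_id for f in features])
    ids = np.array([f.subject_id for f in features])
    return x, y, sites, ids


def write_feature_csv(features: Sequence[FeatureVector], path) -> None:
    """One row per subject: subject_id, site_id, label, f_0 ... f_{D-1}."""
    x, y, sites, ids = stack_features(features)
    df = pd.DataFrame(x, columns=[f"f_{k}" for k in range(x.shape[1])])
    df.insert(0, "label", y)
    df.insert(0, "site_id", sites)
    df.insert(0, "subject_id", ids)
    df.to_csv(path, index=False)


def read_feature_csv(path) -> list[FeatureVector]:
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f_")]
    return [
        FeatureVector(
            subject_id=str(row["subject_id"]),
            site_id=str(row["site_id"]),
            label=int(row["label"]),
            values=row[feat_cols].to_numpy(dtype=float),
        )
        for _, row in df.iterrows()
    ]
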