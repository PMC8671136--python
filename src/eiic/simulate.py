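"""Seeded multi-site, two-class ROI time-series simulator.

The generator emulates the statistical structure a harmonization method must
overcome in multi-site resting-state functional-connectivity data:

* a shared base correlation structure Sigma_0 across all subjects,
* a *class effect*: a fixed subset of edges whose Fisher-z correlation is
  shifted by ``effect_size`` in class-1 (case) subjects,
* *site effects*: an additive mean shift on the z scale applied to every
  edge (scanner/cohort bias), a per-site AR(1) temporal autocorrelation
  standing in for repetition-time differences, and additive white
  measurement noise whose standard deviation is ``noise_scale`` (which
  attenuates observed correlations, as scanner noise does).

Shifts are applied on the z scale, back-transformed through tanh, and the
resulting matrix is projected to the nearest positive-definite correlation
matrix by eigenvalue clipping, so every subject has a valid sampling target.
Time series are drawn from a stationary AR(1) latent process whose
instantaneous covariance equals the target correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import SubjectRecord, fisher_z, lower_triangle_vector

__all__ = ["SiteSpec", "SimSpec", "simulate_dataset", "write_fixture"]

PD_EIG_FLOOR = 1e-6


@dataclass
class SiteSpec:
    """Scanner/cohort profile of one simulated acquisition site."""

    site_id: str
    n_subjects: int
    t_points: int = 150
    noise_scale: float = 0.3
    mean_shift: float = 0.0
    class_ratio: float = 0.5
    ar_coeff: float = 0.3

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("each site needs at least 2 subjects")
        if not 0.0 < self.class_ratio < 1.0:
            raise ValueError("class_ratio must lie in (0, 1)")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.t_points < 2:
            raise ValueError("t_points must be >= 2")


@dataclass
class SimSpec:
    """Full study design: parcellation size, sites, class effect, seed."""

    n_rois: int = 20
    sites: list[SiteSpec] = field(default_factory=list)
    effect_edges: float = 0.2
    effect_size: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if not self.sites:
            raise ValueError("at least one site is required")
        if not 0.0 <= self.effect_edges <= 1.0:
            raise ValueError("effect_edges must lie in [0, 1]")


def _base_correlation(n_rois: int, rng: np.random.Generator) -> np.ndarray:
    """Random low-rank-plus-diagonal correlation matrix with moderate r."""
    loadings = rng.normal(0.0, 1.0, (n_rois, 3))
    cov = loadings @ loadings.T + 4.0 * np.eye(n_rois)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix."""
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, PD_EIG_FLOOR, None)
    pd_mat = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(pd_mat))
    corr = pd_mat / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def _target_correlation(
    z_base: np.ndarray,
    mask: np.ndarray,
    label: int,
    effect_size: float,
    mean_shift: float,
    n_rois: int,
) -> np.ndarray:
    z = z_base.copy()
    if label == 1:
        z[mask] += effect_size
    z += mean_shift
    mat = np.eye(n_rois)
    i, j = np.tril_indices(n_rois, k=-1)
    mat[i, j] = mat[j, i] = np.tanh(z)
    return _nearest_correlation(mat)


def _ar1_series(
    chol: np.ndarray,
    t_points: int,
    ar: float,
    noise_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary AR(1) draw with instantaneous covariance chol @ chol.T."""
    n_rois = chol.shape[0]
    innov = rng.standard_normal((t_points, n_rois)) @ chol.T
    x = np.empty((t_points, n_rois))
    x[0] = innov[0]
    scale = np.sqrt(1.0 - ar * ar)
    for t in range(1, t_points):
        x[t] = ar * x[t - 1] + scale * innov[t]
    if noise_scale > 0:
        x = x + noise_scale * rng.standard_normal(x.shape)
    return x


def simulate_dataset(spec: SimSpec) -> tuple[list[SubjectRecord], np.ndarray]:
    """Generate subject records plus the ground-truth affected-edge mask.

    The mask is a boolean vector over the R(R-1)/2 strictly-lower-triangular
    edges in the same row-major order :func:`~eiic.features.lower_triangle_vector`
    uses; its cardinality is exactly ``round(effect_edges * n_edges)``.
    """
    rng = np.random.default_rng(spec.seed)
    n_edges = spec.n_rois * (spec.n_rois - 1) // 2
    sigma0 = _base_correlation(spec.n_rois, rng)
    z_base = fisher_z(lower_triangle_vector(sigma0))
    n_affected = int(round(spec.effect_edges * n_edges))
    mask = np.zeros(n_edges, dtype=bool)
    mask[rng.choice(n_edges, size=n_affected, replace=False)] = True

    records: list[SubjectRecord] = []
    chol_cache: dict[tuple[str, int], np.ndarray] = {}
    for site in spec.sites:
        n1 = int(round(site.class_ratio * site.n_subjects))
        labels = np.array([1] * n1 + [0] * (site.n_subjects - n1))
        labels = labels[rng.permutation(site.n_subjects)]
        for k, label in enumerate(labels):
            subject_id = f"{site.site_id}_{k:03d}"
            key = (site.site_id, int(label))
            if key not in chol_cache:
                target = _target_correlation(
                    z_base, mask, int(label), spec.effect_size, site.mean_shift, spec.n_rois
                )
                if not np.all(np.isfinite(target)):
                    raise ValueError(
                        f"target correlation for subject {subject_id} is not projectable"
                    )
                chol_cache[key] = np.linalg.cholesky(target)
            ts = _ar1_series(
                chol_cache[key], site.t_points, site.ar_coeff, site.noise_scale, rng
            )
            records.append(
                SubjectRecord(
                    subject_id=subject_id,
                    site_id=site.site_id,
                    label=int(label),
                    timeseries=ts,
                )
            )
    return records, mask


def write_fixture(records: list[SubjectRecord], directory) -> None:
    """Write one ``.1D``-dialect file per subject plus a phenotype CSV.

    The phenotype table uses the ABIDE diagnosis coding (1 = case, 2 =
    control) with columns SUB_ID, SITE_ID, DX_GROUP; site membership lives in
    the phenotype table, not in the filenames.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    rows = []
    for rec in records:
        path = os.path.join(directory, f"{rec.subject_id}_rois.1D")
        n_rois = rec.timeseries.shape[1]
        header = " ".join(f"ROI_{k + 1:03d}" for k in range(n_rois))
        np.savetxt(path, rec.timeseries, fmt="%.6f", header=header)
        rows.append(
            {
                "SUB_ID": rec.subject_id,
                "SITE_ID": rec.site_id,
                "DX_GROUP": 1 if rec.label == 1 else 2,
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(directory, "phenotype.csv"), index=False)
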