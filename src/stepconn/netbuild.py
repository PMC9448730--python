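"""Subject-level voxelwise association matrix.

Pearson correlation between every pair of in-mask voxel time courses, Fisher
z transform, one-sided edge p-values for positive association, and
Benjamini-Hochberg FDR thresholding over the upper-triangle edge family.
The final matrix A keeps the Fisher-z value on retained edges (positive,
FDR-significant) and is zero elsewhere — nonnegative, symmetric, zero
diagonal, ready for the stepwise-connectivity recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationMatrix",
    "correlation_matrix",
    "edge_pvalues",
    "fdr_threshold",
    "assemble",
    "build_association_matrix",
]

#: Fisher z is undefined at |r| = 1 (duplicated voxels); such edges carry this
#: sentinel in ``z`` and are excluded from the edge family.
Z_CAP = 18.0  # atanh(1 - 1e-16) overflows; tanh(18) == 1.0 at float64


@dataclass
class AssociationMatrix:
    """Thresholded nonnegative connectivity matrix with its provenance."""

    r: np.ndarray
    z: np.ndarray
    p: np.ndarray
    A: np.ndarray
    df: int
    q: float
    two_sided: bool = False

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def density(self) -> float:
        m = self.m
        if m < 2:
            return 0.0
        return float((self.A > 0).sum() / (m * (m - 1)))

    def validate(self) -> None:
        if not np.allclose(self.A, self.A.T):
            raise ValueError("A must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("A must have a zero diagonal")
        if np.any(self.A < 0):
            raise ValueError("A must be nonnegative")


def correlation_matrix(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-by-voxel Pearson r and Fisher z for an (m, t) series matrix.

    Zero-variance voxels are an error (their correlation is undefined); the
    message lists the offending voxel indices.  ``z`` is ``atanh(r)`` off the
    diagonal, with |r| = 1 capped at ``Z_CAP``; the diagonal of ``z`` is 0.
    """
    series = np.asarray(series, float)
    if series.ndim != 2:
        raise ValueError("series must be (m voxels, t volumes)")
    if series.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    sd = series.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance voxels at indices {dead.tolist()}")
    r = np.corrcoef(series)
    r = np.clip(r, -1.0, 1.0)
    # snap numerically-perfect correlations (duplicated voxels) to exactly +-1
    # so the sentinel path is robust to rounding
    snap = np.abs(r) >= 1.0 - 1e-12
    r[snap] = np.sign(r[snap])
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z[np.abs(r) >= 1.0] = np.sign(r[np.abs(r) >= 1.0]) * Z_CAP
    np.fill_diagonal(z, 0.0)
    return r, z


def edge_pvalues(r: np.ndarray, n_timepoints: int, two_sided: bool = False) -> np.ndarray:
    """Per-edge p-values from the t transform of the correlation.

    Default is the one-sided test of positive association,
    ``t = r sqrt((n-2)/(1-r^2))`` on ``n - 2`` degrees of freedom (so r = 0
    gives p = 0.5 and strongly negative r gives p near 1).  ``|r| = 1`` maps
    to p = 0 by convention.  The diagonal is set to 1 (never an edge).
    """
    if n_timepoints <= 3:
        raise ValueError("need more than 3 time points")
    r = np.asarray(r, float)
    df = n_timepoints - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    if two_sided:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = stats.t.sf(t, df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.asarray(p, float)
    if p.ndim == 2:
        np.fill_diagonal(p, 1.0)
    return p


def fdr_threshold(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask for a flat p-value vector."""
    p = np.asarray(p, float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def assemble(z: np.ndarray, reject: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Final association matrix: Fisher z on retained positive edges, else 0.

    ``reject`` is the upper-triangle rejection mask (vector over i < j edges).
    Perfect-correlation sentinel edges (|r| = 1 off-diagonal, i.e. duplicated
    voxels) are excluded.
    """
    z = np.asarray(z, float)
    r = np.asarray(r, float)
    m = z.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    if reject.shape != iu.shape:
        raise ValueError("rejection mask must cover the upper-triangle edges")
    keep = reject & (r[iu, ju] > 0) & (np.abs(r[iu, ju]) < 1.0)
    A = np.zeros_like(z)
    A[iu[keep], ju[keep]] = z[iu[keep], ju[keep]]
    A = A + A.T
    return A


def build_association_matrix(series: np.ndarray, q: float = 0.05,
                             two_sided: bool = False) -> AssociationMatrix:
    """Cleaned series (m, t) -> thresholded association matrix, in one call.

    Degrees of freedom are taken as ``n_timepoints - 2``; autocorrelation left
    by band-pass filtering is not corrected for (a known simplification —
    stated calibration properties hold for serially uncorrelated data).
    """
    series = np.asarray(series, float)
    n = series.shape[1]
    r, z = correlation_matrix(series)
    p = edge_pvalues(r, n, two_sided=two_sided)
    iu, ju = np.triu_indices(r.shape[0], k=1)
    reject = fdr_threshold(p[iu, ju], q=q)
    A = assemble(z, reject, r)
    out = AssociationMatrix(r=r, z=z, p=p, A=A, df=n - 2, q=q, two_sided=two_sided)
    out.validate()
    return out
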