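"""Stepwise functional connectivity: walk-count matrices and seed maps.

The stepwise connectivity degree of voxel ``j`` at link-step distance ``l``
from a seed area counts (with weights) all paths of exact length ``l``
between ``j`` and any seed voxel.  With A the thresholded Fisher-z
association matrix, the step-l matrix is built recursively:

    A_1(i, j) = A(i, j)                                   (i != j)
    A_l(i, j) = sum_k norm(A_{l-1})(i, k) * norm(A)(k, j) (i != j, l >= 2)

where ``norm`` is min-max scaling of the off-diagonal entries to [0, 1],
applied at every step so maps are comparable across step distances.  Walks
may revisit voxels and the seed; there is no simple-path pruning.  On a
binary matrix the scaling is affine in the 2-walk count, so A_2 reduces to
the classical off-diagonal matrix square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepwiseMatrixSet",
    "SFCMap",
    "minmax_offdiag",
    "stepwise_matrices",
    "seed_map",
    "stability_profile",
]


def minmax_offdiag(M: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Min-max scale the off-diagonal entries of a square matrix to [0, 1].

    The diagonal is excluded from the min/max (it is undefined in the
    recursion) and set to 0 in the output so walks never stay in place.
    A constant off-diagonal (max == min) maps to all zeros, which terminates
    propagation of degenerate matrices instead of dividing by zero.
    """
    M = np.asarray(M, float)
    m = M.shape[0]
    off = ~np.eye(m, dtype=bool)
    vals = M[off]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros_like(M)
    if hi > lo:
        out[off] = (vals - lo) / (hi - lo)
    return out, lo, hi


@dataclass
class StepwiseMatrixSet:
    """Raw step matrices A_l plus the per-step min/max normalizers.

    ``raw[1]`` is the input A itself (off-diagonal); for ``l >= 2`` the raw
    matrix is the product of the normalized previous step with the normalized
    A.  ``normalized(l)`` returns the [0, 1]-scaled version used both for the
    next recursion step and for seed maps.
    """

    raw: dict[int, np.ndarray]
    minmax: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def L_max(self) -> int:
        return max(self.raw)

    def normalized(self, l: int) -> np.ndarray:
        out, lo, hi = minmax_offdiag(self.raw[l])
        self.minmax[l] = (lo, hi)
        return out


@dataclass
class SFCMap:
    """Seed-based stepwise degree maps s_l(j) for l = 1..L."""

    seed: np.ndarray              # sorted in-mask voxel indices of the seed
    maps: dict[int, np.ndarray]   # l -> per-voxel degree (length m)
    seed_flag: np.ndarray         # True on seed voxels (values reported, flagged)

    @property
    def L_max(self) -> int:
        return max(self.maps)


def stepwise_matrices(A: np.ndarray, L_max: int) -> StepwiseMatrixSet:
    """Run the recursion up to ``L_max`` link steps.

    An all-zero A yields all-zero step matrices (with a warning, not an
    error): a fully disconnected network has no walks at any distance.
    Positive rescaling of A leaves every normalized A_l unchanged — min-max
    scaling removes the scale.
    """
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    if not A.any():
        import warnings
        warnings.warn("association matrix is all zero; all step matrices are zero")
    raw: dict[int, np.ndarray] = {}
    A1 = A.copy()
    np.fill_diagonal(A1, 0.0)
    raw[1] = A1
    stepset = StepwiseMatrixSet(raw)
    if L_max == 1:
        return stepset
    normA = stepset.normalized(1)
    prev = normA
    offdiag = ~np.eye(A.shape[0], dtype=bool)
    for l in range(2, L_max + 1):
        Al = prev @ normA
        Al[~offdiag] = 0.0
        raw[l] = Al
        prev = stepset.normalized(l)
    return stepset


def seed_map(stepset: StepwiseMatrixSet, seed: np.ndarray,
             m: int | None = None, aggregate: str = "sum") -> SFCMap:
    """Aggregate normalized step matrices over a seed area.

    ``s_l(j) = sum_{i in seed} A_l(i, j)`` (or the mean over seed voxels with
    ``aggregate='mean'``).  Seed voxels get a value like any other target but
    are flagged so downstream statistics can exclude them.
    """
    seed = np.unique(np.asarray(seed, int))
    if seed.size == 0:
        raise ValueError("seed is empty")
    m = m or stepset.raw[1].shape[0]
    if seed.min() < 0 or seed.max() >= m:
        raise ValueError("seed indices fall outside the analysis mask")
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    flag = np.zeros(m, dtype=bool)
    flag[seed] = True
    maps: dict[int, np.ndarray] = {}
    for l in sorted(stepset.raw):
        Al = stepset.normalized(l)
        s = Al[seed].sum(axis=0)
        if aggregate == "mean":
            s = s / seed.size
        maps[l] = s
    return SFCMap(seed=seed, maps=maps, seed_flag=flag)


def stability_profile(sfc: SFCMap, include_seed: bool = False) -> dict[int, float]:
    """Spatial Pearson correlation between consecutive step maps.

    Returns ``{l: corr(s_l, s_{l+1})}`` over non-seed in-mask voxels (seed
    voxels included on request).  A constant map makes the correlation
    undefined; such entries are reported as NaN.  As ``l`` grows the
    normalized recursion is a power iteration, so on a generic connected
    positive matrix the profile approaches 1.
    """
    steps = sorted(sfc.maps)
    if len(steps) < 2:
        raise ValueError("need at least 2 step maps")
    keep = slice(None) if include_seed else ~sfc.seed_flag
    out: dict[int, float] = {}
    for a, b in zip(steps[:-1], steps[1:]):
        x, y = sfc.maps[a][keep], sfc.maps[b][keep]
        if x.std() == 0 or y.std() == 0:
            out[a] = float("nan")
        else:
            out[a] = float(np.corrcoef(x, y)[0, 1])
    return out
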