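"""Task-based definition of the motor seed region.

A block-design motor task (alternating ~19 s activation/rest periods) is
analysed with a voxelwise GLM: the boxcar is convolved with a canonical
double-gamma haemodynamic response, subject-level contrast maps feed a group
one-sample t-test, and the thresholded group map (p < 0.001 uncorrected at
the voxel, small clusters removed) is downsampled by majority vote to the
5 mm analysis grid to yield the seed mask for stepwise connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "BlockDesign",
    "ActivationMap",
    "hrf_double_gamma",
    "design_matrix",
    "fit_glm_tmap",
    "group_tmap",
    "threshold_to_seed",
]


def hrf_double_gamma(dt: float, duration_s: float = 32.0, peak_s: float = 6.0,
                     undershoot_s: float = 16.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, peak-normalized.

    Gamma shapes ``peak_s`` and ``undershoot_s`` with unit scale, mixed with
    ``ratio`` — the conventional kernel of volumetric fMRI packages (response
    mode near 5 s, undershoot near 15 s).
    """
    t = np.arange(0, duration_s, dt)
    pos = stats.gamma.pdf(t, a=peak_s, scale=1.0)
    neg = stats.gamma.pdf(t, a=undershoot_s, scale=1.0)
    h = pos - ratio * neg
    return h / h.max()


@dataclass
class BlockDesign:
    """Timing of the activation condition in a block design."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    tr_seconds: float
    n_volumes: int
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        self.onsets_s = np.atleast_1d(np.asarray(self.onsets_s, float))
        self.durations_s = np.atleast_1d(np.asarray(self.durations_s, float))
        if self.durations_s.size == 1:
            self.durations_s = np.repeat(self.durations_s, self.onsets_s.size)
        if self.onsets_s.shape != self.durations_s.shape:
            raise ValueError("onsets and durations must align")

    @classmethod
    def abab(cls, block_s: float, n_cycles: int, tr_seconds: float) -> "BlockDesign":
        """Alternating A/B blocks of equal length, A first, period 2*block_s."""
        onsets = np.arange(n_cycles) * 2.0 * block_s
        n_vol = int(np.ceil(2.0 * block_s * n_cycles / tr_seconds))
        return cls(onsets, np.full(n_cycles, block_s), tr_seconds, n_vol)


def design_matrix(block: BlockDesign, oversample: int = 16) -> np.ndarray:
    """GLM design: HRF-convolved boxcar, intercept, linear drift.

    The boxcar is built on a fine grid (``tr/oversample``), convolved with the
    canonical HRF and sampled at volume acquisition times.  Zero-duration
    blocks (an identically zero regressor) and blocks running past the end of
    the scan are errors.
    """
    scan_s = block.n_volumes * block.tr_seconds
    if np.any(block.onsets_s + block.durations_s > scan_s + 1e-9):
        raise ValueError("task blocks exceed the scan duration")
    if np.all(block.durations_s <= 0):
        raise ValueError("zero-duration blocks produce an all-zero regressor")
    dt = block.tr_seconds / oversample
    n_fine = int(np.ceil(scan_s / dt))
    box = np.zeros(n_fine)
    tt = np.arange(n_fine) * dt
    for on, dur in zip(block.onsets_s, block.durations_s):
        box[(tt >= on) & (tt < on + dur)] = 1.0
    h = hrf_double_gamma(dt, peak_s=block.hrf_peak_s,
                         undershoot_s=block.hrf_undershoot_s,
                         ratio=block.hrf_ratio)
    conv = np.convolve(box, h)[:n_fine]
    sample_idx = np.round(np.arange(block.n_volumes) * block.tr_seconds / dt).astype(int)
    task = conv[np.clip(sample_idx, 0, n_fine - 1)]
    n = block.n_volumes
    drift = np.arange(n, dtype=float)
    drift = (drift - drift.mean()) / max(drift.std(), 1.0)
    return np.column_stack([task, np.ones(n), drift])


@dataclass
class ActivationMap:
    tstat: np.ndarray            # per-voxel t, flat over in-mask voxels
    df: int
    mask: np.ndarray             # analysis mask (3D)
    seed_mask: np.ndarray | None = None   # thresholded binary mask (3D)
    capped: bool = field(default=False)   # any |t| capped at T_CAP


#: Numerical cap on reported |t| (perfect fits give unbounded statistics).
T_CAP = 1e6


def fit_glm_tmap(series: np.ndarray, design: np.ndarray,
                 contrast: np.ndarray | None = None) -> tuple[np.ndarray, int, bool]:
    """Per-voxel OLS t for the task contrast; returns (t, df, capped_flag)."""
    X = np.asarray(design, float)
    Y = np.asarray(series, float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("task design is rank deficient")
    if contrast is None:
        contrast = np.zeros(X.shape[1])
        contrast[0] = 1.0
    c = np.asarray(contrast, float)
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y.T
    resid = Y.T - X @ beta
    df = n - p
    s2 = (resid ** 2).sum(axis=0) / df
    denom2 = s2 * float(c @ XtX_inv @ c)
    cb = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom2 > 0, cb / np.sqrt(denom2), np.sign(cb) * np.inf)
    capped = bool(np.any(np.abs(t) > T_CAP))
    t = np.clip(t, -T_CAP, T_CAP)
    return t, df, capped


def group_tmap(contrast_maps: np.ndarray) -> tuple[np.ndarray, int]:
    """One-sample t across subjects' first-level contrast values (n, m)."""
    Y = np.asarray(contrast_maps, float)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = Y.mean(axis=0)
    se = Y.std(axis=0, ddof=1) / np.sqrt(n)
    t = np.zeros(Y.shape[1])
    ok = se > 0
    t[ok] = mean[ok] / se[ok]
    return t, n - 1


def _downsample_majority(mask: np.ndarray, factor: int) -> np.ndarray:
    """Block-wise majority vote: a coarse voxel is set when >= 50% of its
    fine-grid block is in the mask.  Grid dimensions must divide by factor."""
    m = np.asarray(mask, bool)
    if any(s % factor for s in m.shape):
        raise ValueError(f"grid {m.shape} not divisible by factor {factor}")
    z, y, x = (s // factor for s in m.shape)
    blocks = m.reshape(z, factor, y, factor, x, factor)
    frac = blocks.mean(axis=(1, 3, 5))
    return frac >= 0.5


def threshold_to_seed(tmap: np.ndarray, df: int, mask: np.ndarray | None = None,
                      p_voxel: float = 0.001, min_cluster: int = 10,
                      downsample_factor: int = 1) -> np.ndarray:
    """Group t-map -> binary seed mask on the analysis grid.

    One-sided threshold at the t quantile for ``p_voxel``; clusters smaller
    than ``min_cluster`` voxels (26-connectivity) are removed, then the mask
    is downsampled by majority vote.  An empty result is returned with a
    warning (downstream seed mapping raises on an empty seed).
    """
    tmap = np.asarray(tmap, float)
    if not np.all(np.isfinite(tmap)):
        raise ValueError("t-map must be finite")
    t_crit = stats.t.isf(p_voxel, df)
    supra = tmap > t_crit
    if mask is not None:
        supra &= np.asarray(mask, bool)
    labels, n_lab = ndimage.label(supra, structure=np.ones((3, 3, 3), bool))
    if n_lab:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_cluster)
        supra[np.isin(labels, small[small > 0])] = False
    if downsample_factor > 1:
        supra = _downsample_majority(supra, downsample_factor)
    if not supra.any():
        import warnings
        warnings.warn("no suprathreshold cluster survived; seed mask is empty")
    return supra
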