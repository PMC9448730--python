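"""End-to-end drivers tying the stages together.

``subject_sfc_maps`` takes one subject's (cleaned or raw) voxel time series
to seed-based stepwise maps; ``cohort_sfc_maps`` stacks them for a cohort so
the group model and the ROC analysis can run directly on the output.
"""

from __future__ import annotations

import numpy as np

from . import netbuild, preprocess, sfc
from .synth import NetworkBlueprint, VoxelTimeSeries

__all__ = ["subject_sfc_maps", "cohort_sfc_maps", "seed_indices"]


def seed_indices(seed_mask: np.ndarray, analysis_mask: np.ndarray) -> np.ndarray:
    """Flat in-mask voxel indices of a 3D seed mask."""
    seed_mask = np.asarray(seed_mask, bool)
    analysis_mask = np.asarray(analysis_mask, bool)
    if np.any(seed_mask & ~analysis_mask):
        raise ValueError("seed mask extends outside the analysis mask")
    flat = seed_mask[analysis_mask]
    idx = np.flatnonzero(flat)
    if idx.size == 0:
        raise ValueError("seed mask is empty inside the analysis mask")
    return idx


def subject_sfc_maps(series: np.ndarray, seed: np.ndarray, L_max: int = 4,
                     q: float = 0.05, aggregate: str = "sum") -> sfc.SFCMap:
    """Series (m, t) -> association matrix -> stepwise seed maps."""
    assoc = netbuild.build_association_matrix(series, q=q)
    steps = sfc.stepwise_matrices(assoc.A, L_max)
    return sfc.seed_map(steps, seed, aggregate=aggregate)


def cohort_sfc_maps(series_list: list[VoxelTimeSeries] | list[np.ndarray],
                    seed: np.ndarray, L_max: int = 4, q: float = 0.05,
                    motion_list: list[np.ndarray] | None = None,
                    tr_seconds: float = 3.0,
                    run_preprocess: bool = False) -> dict[int, np.ndarray]:
    """Per-step stacked maps ``{l: (n_subjects, m)}`` for a cohort.

    With ``run_preprocess`` the full cleaning driver (volume drop, nuisance
    regression incl. scrubbing spikes, band-pass) runs first; otherwise the
    series are used as-is (the synthetic generator emits already-clean data).
    """
    maps: dict[int, list[np.ndarray]] = {l: [] for l in range(1, L_max + 1)}
    for i, ts in enumerate(series_list):
        data = ts.data if isinstance(ts, VoxelTimeSeries) else np.asarray(ts, float)
        tr = ts.tr_seconds if isinstance(ts, VoxelTimeSeries) else tr_seconds
        if run_preprocess:
            motion = motion_list[i] if motion_list is not None else np.zeros((data.shape[1], 6))
            clean = preprocess.clean_subject(data, motion, tr)
            data = clean.data
        smap = subject_sfc_maps(data, seed, L_max=L_max, q=q)
        for l in range(1, L_max + 1):
            maps[l].append(smap.maps[l])
    return {l: np.vstack(v) for l, v in maps.items()}
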