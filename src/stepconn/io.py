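"""File-format plumbing: NIfTI volumes, rp-dialect motion text, cohort CSV."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "load_bold",
    "load_mask",
    "save_volume",
    "save_series",
    "load_motion",
    "load_cohort",
]


def load_bold(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """4D NIfTI -> (data, affine, TR seconds)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    return data, img.affine, tr


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    return data > 0, img.affine


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def save_series(path: str | Path, data: np.ndarray, mask: np.ndarray,
                affine: np.ndarray | None = None, tr_seconds: float | None = None) -> None:
    """Flat (m, t) in-mask series -> 4D NIfTI."""
    vol = np.zeros(mask.shape + (data.shape[1],), dtype=np.float32)
    vol[np.asarray(mask, bool)] = data
    img = nib.Nifti1Image(vol, affine if affine is not None else np.eye(4))
    if tr_seconds:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_seconds
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_motion(path: str | Path) -> np.ndarray:
    """SPM rp-dialect motion text: 6 whitespace-delimited columns
    (translations mm, then rotations rad)."""
    params = np.loadtxt(str(path))
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got shape {params.shape}")
    return params


def load_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {sorted(missing)}")
    return df
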