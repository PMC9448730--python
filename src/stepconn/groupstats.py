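"""Voxelwise between-group inference on stepwise connectivity maps.

A general linear model is fitted per voxel (group indicator plus age and sex
covariates), the group contrast t-map is enhanced with TFCE, and family-wise
error is controlled with the permutation distribution of the image-wide
maximum TFCE statistic.  Permutations follow the Freedman-Lane scheme: maps
are residualized on the nuisance covariates and the residual rows are
permuted, so age/sex structure is respected under the null.

Each contrast direction (increased / decreased connectivity) is tested with
its own max-null distribution; each link-step map is its own family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tfce import TFCEParams, neighbor_csr, tfce_masked

__all__ = [
    "GroupDesign",
    "TFCEParams",
    "InferenceResult",
    "glm_contrast_tmap",
    "permutation_fwe",
    "StepwiseGroupModel",
]


@dataclass
class GroupDesign:
    """Design matrix, contrast vector and column names for one comparison."""

    X: np.ndarray
    contrast: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.contrast = np.asarray(self.contrast, float)
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length must equal design column count")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            bad = [n for j, n in enumerate(self.names)
                   if np.std(self.X[:, j]) == 0 and n != "intercept"]
            raise ValueError(f"design is rank deficient (constant/collinear columns: {bad})")

    @classmethod
    def from_table(cls, table: pd.DataFrame, groups: tuple[str, str],
                   covariates: tuple[str, ...] = ("age", "sex")) -> "GroupDesign":
        """Two-sample contrast ``groups[0] - groups[1]`` with covariates.

        ``sex`` is dummy-coded (F=0, M=1) if non-numeric.  Rows of ``table``
        must be in map order and belong to one of the two groups.
        """
        g = table["group"].to_numpy()
        if not np.isin(g, groups).all():
            raise ValueError(f"table contains groups outside {groups}")
        cols = [np.ones(len(table)), (g == groups[0]).astype(float)]
        names = ["intercept", f"{groups[0]}-{groups[1]}"]
        for cov in covariates:
            v = table[cov]
            if v.dtype == object:
                v = (v == v.iloc[0]).astype(float)
            col = np.asarray(v, float)
            cols.append(col - col.mean())
            names.append(cov)
        X = np.column_stack(cols)
        c = np.zeros(X.shape[1])
        c[1] = 1.0
        return cls(X, c, names)

    def flipped(self) -> "GroupDesign":
        return GroupDesign(self.X, -self.contrast, self.names)


def glm_contrast_tmap(maps: np.ndarray, design: GroupDesign) -> tuple[np.ndarray, int]:
    """Per-voxel OLS contrast t-map for subject maps (n_subjects, m).

    ``t = c'b / sqrt(s2 * c'(X'X)^-1 c)`` with ``df = n - rank(X)``.  Voxels
    with zero residual variance get t = 0 (no evidence either way).
    """
    Y = np.asarray(maps, float)
    X, c = design.X, design.contrast
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("one map per design row required")
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p
    s2 = (resid ** 2).sum(axis=0) / df
    denom2 = s2 * float(c @ XtX_inv @ c)
    t = np.zeros(Y.shape[1])
    ok = denom2 > 0
    t[ok] = (c @ beta)[ok] / np.sqrt(denom2[ok])
    return t, df


@dataclass
class InferenceResult:
    """Raw t-map, TFCE map, voxelwise FWE p and the significant-voxel mask."""

    tstat: np.ndarray
    tfce: np.ndarray
    fwe_p: np.ndarray
    sig_mask: np.ndarray
    n_perm: int
    df: int
    alpha: float = 0.05
    max_null: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)


def permutation_fwe(maps: np.ndarray, design: GroupDesign, mask: np.ndarray,
                    params: TFCEParams | None = None, n_perm: int = 5000,
                    seed: int | np.random.Generator | None = None,
                    alpha: float = 0.05) -> InferenceResult:
    """Permutation FWE inference for one contrast direction.

    ``maps`` is (n_subjects, m) over the in-mask voxels of the 3D ``mask``.
    The positive part of the contrast t-map is TFCE-enhanced; the null is the
    per-permutation image-wide maximum TFCE, so
    ``FWE p(v) = (1 + #{max_null >= TFCE(v)}) / (n_perm + 1)``.
    """
    params = params or TFCEParams()
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    mask = np.asarray(mask, bool)
    maps = np.asarray(maps, float)
    if maps.shape[1] != int(mask.sum()):
        raise ValueError("map length must equal in-mask voxel count")
    n = maps.shape[0]
    counts = np.unique(design.X[:, np.flatnonzero(design.contrast)[0]],
                       return_counts=True)[1]
    if counts.min(initial=n) < 3:
        import warnings
        warnings.warn("a group has fewer than 3 subjects; the permutation space is tiny")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nptr, nidx = neighbor_csr(mask, params.connectivity)

    tstat, df = glm_contrast_tmap(maps, design)
    tfce_obs = tfce_masked(tstat, nptr, nidx, params)

    # Freedman-Lane: residualize on the reduced (nuisance-only) model
    nuis = design.contrast == 0
    Z = design.X[:, nuis]
    R = maps - Z @ (np.linalg.pinv(Z) @ maps)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        t_b, _ = glm_contrast_tmap(R[perm], design)
        max_null[b] = tfce_masked(t_b, nptr, nidx, params).max(initial=0.0)
    exceed = (max_null[None, :] >= tfce_obs[:, None]).sum(axis=1)
    fwe_p = (1.0 + exceed) / (n_perm + 1.0)
    return InferenceResult(tstat=tstat, tfce=tfce_obs, fwe_p=fwe_p,
                           sig_mask=fwe_p < alpha, n_perm=n_perm, df=df,
                           alpha=alpha, max_null=max_null)


class StepwiseGroupModel:
    """Between-group model for one link-step's seed maps.

    Parameters
    ----------
    maps : (n_subjects, m) array of per-subject stepwise degree values.
    design : GroupDesign (or a cohort table via ``from_table``).
    mask : 3D boolean analysis mask with m True voxels.
    tfce_params : TFCE parameterization (H=2, E=0.5, dh=max/100, 26-conn).
    """

    def __init__(self, maps: np.ndarray, design: GroupDesign, mask: np.ndarray,
                 tfce_params: TFCEParams | None = None):
        self.maps = np.asarray(maps, float)
        self.design = design
        self.mask = np.asarray(mask, bool)
        self.tfce_params = tfce_params or TFCEParams()

    @classmethod
    def from_table(cls, maps: np.ndarray, table: pd.DataFrame,
                   groups: tuple[str, str], mask: np.ndarray,
                   covariates: tuple[str, ...] = ("age", "sex"),
                   tfce_params: TFCEParams | None = None) -> "StepwiseGroupModel":
        return cls(maps, GroupDesign.from_table(table, groups, covariates),
                   mask, tfce_params)

    def fit(self, n_perm: int = 5000, seed: int | None = None,
            alpha: float = 0.05, directions: tuple[str, ...] = ("increase", "decrease"),
            ) -> "StepwiseGroupResults":
        """Run both contrast directions, each with its own max-null."""
        rng = np.random.default_rng(seed)
        results: dict[str, InferenceResult] = {}
        for d in directions:
            dsg = self.design if d == "increase" else self.design.flipped()
            results[d] = permutation_fwe(self.maps, dsg, self.mask,
                                         self.tfce_params, n_perm, rng, alpha)
        return StepwiseGroupResults(self, results)


class StepwiseGroupResults:
    """Fitted group comparison: per-direction inference plus a cluster table."""

    def __init__(self, model: StepwiseGroupModel, results: dict[str, InferenceResult]):
        self.model = model
        self.results = results

    def __getitem__(self, direction: str) -> InferenceResult:
        return self.results[direction]

    def significance_mask(self, direction: str | None = None) -> np.ndarray:
        """3D boolean mask of FWE-significant voxels (union over directions)."""
        mask3 = np.zeros(self.model.mask.shape, dtype=bool)
        dirs = [direction] if direction else list(self.results)
        flat = np.zeros(int(self.model.mask.sum()), dtype=bool)
        for d in dirs:
            flat |= self.results[d].sig_mask
        mask3[self.model.mask] = flat
        return mask3

    def signed_significance_mask(self) -> np.ndarray:
        """3D int8 mask: +1 where increased connectivity is significant,
        -1 where decreased is (increase wins the rare overlap), else 0."""
        out = np.zeros(self.model.mask.shape, dtype=np.int8)
        if "decrease" in self.results:
            flat = np.zeros(int(self.model.mask.sum()), dtype=np.int8)
            flat[self.results["decrease"].sig_mask] = -1
            out[self.model.mask] = flat
        if "increase" in self.results:
            flat = out[self.model.mask]
            flat[self.results["increase"].sig_mask] = 1
            out[self.model.mask] = flat
        return out

    def cluster_table(self) -> pd.DataFrame:
        """Significant clusters: direction, size, peak |t|, peak FWE p, peak voxel."""
        from scipy import ndimage

        rows = []
        struct = np.ones((3, 3, 3), bool)
        coords = np.argwhere(self.model.mask)
        for d, res in self.results.items():
            vol = np.zeros(self.model.mask.shape, bool)
            vol[self.model.mask] = res.sig_mask
            labels, n_lab = ndimage.label(vol, structure=struct)
            flat_lab = labels[self.model.mask]
            for k in range(1, n_lab + 1):
                sel = flat_lab == k
                peak = np.argmax(np.abs(res.tstat) * sel)
                rows.append({
                    "direction": d, "cluster": k, "size": int(sel.sum()),
                    "peak_t": float(res.tstat[peak]),
                    "peak_fwe_p": float(res.fwe_p[peak]),
                    "peak_voxel": tuple(int(c) for c in coords[peak]),
                })
        return pd.DataFrame(rows, columns=["direction", "cluster", "size",
                                           "peak_t", "peak_fwe_p", "peak_voxel"])

    def summary(self) -> str:
        lines = ["Stepwise connectivity group comparison",
                 f"  n subjects: {self.model.maps.shape[0]}, "
                 f"voxels: {self.model.maps.shape[1]}"]
        for d, res in self.results.items():
            lines.append(f"  {d}: {int(res.sig_mask.sum())} significant voxels "
                         f"(FWE p < {res.alpha}, {res.n_perm} permutations, df={res.df})")
        tab = self.cluster_table()
        if len(tab):
            lines.append(tab.to_string(index=False))
        return "\n".join(lines)
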