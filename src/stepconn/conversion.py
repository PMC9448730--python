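"""ROC prediction of tremor-dominant -> PIGD subtype conversion.

Features are the clinical scores that differ at study entry (Hoehn & Yahr,
UPDRS total, FOG questionnaire) and the mean stepwise connectivity within
each significant cluster of the converter-vs-non-converter comparison, at
the direct (1 link-step) and indirect (4 link-steps) distances.  Feature
sets are scored separately and combined; multi-feature sets are combined by
an L2-regularized logistic score on z-scored features, fitted in sample (a
leave-one-out mode is available and is the honest choice at n ~ 28).  ROC
curves, trapezoid AUC (= the Mann-Whitney statistic with ties counted 1/2)
and stratified-bootstrap confidence intervals quantify discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FeatureTable",
    "RocResult",
    "extract_features",
    "combine_score",
    "roc_auc",
    "ConversionModel",
]

CLINICAL_FEATURES = ("HY", "UPDRS_total", "FOGQ")


@dataclass
class FeatureTable:
    """Per-subject features plus the converter label (1 = converter)."""

    features: pd.DataFrame
    labels: np.ndarray
    clinical_names: list[str] = field(default_factory=lambda: list(CLINICAL_FEATURES))
    direct_names: list[str] = field(default_factory=list)
    indirect_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if len(self.features) != self.labels.size:
            raise ValueError("one label per feature row required")
        if not np.isfinite(self.features.to_numpy(float)).all():
            raise ValueError("features must be finite")

    def set_names(self, which: str) -> list[str]:
        sets = {
            "clinical": self.clinical_names,
            "direct": self.direct_names,
            "indirect": self.indirect_names,
            "sfc": self.direct_names + self.indirect_names,
            "combined": (self.clinical_names + self.direct_names
                         + self.indirect_names),
        }
        if which not in sets:
            raise ValueError(f"unknown feature set {which!r}; choose from {list(sets)}")
        return sets[which]


def _cluster_means(maps: np.ndarray, sig_mask: np.ndarray,
                   analysis_mask: np.ndarray) -> np.ndarray:
    """Mean map value per connected cluster of the significance mask.

    ``sig_mask`` may be boolean or signed (+1 increase / -1 decrease
    direction labels).  Clusters use 26-connectivity within each direction;
    features from decrease-direction clusters are sign-flipped so a higher
    feature always points toward the first (affected) group.  Returns
    (n_subjects, n_clusters).
    """
    sig = np.asarray(sig_mask)
    signs = [1] if sig.dtype == bool else [s for s in (1, -1) if (sig == s).any()]
    analysis_mask = np.asarray(analysis_mask, bool)
    cols: list[np.ndarray] = []
    struct = np.ones((3, 3, 3), bool)
    for sgn in signs:
        part = sig.astype(bool) if sig.dtype == bool else sig == sgn
        labels, n_lab = ndimage.label(part, structure=struct)
        flat_lab = labels[analysis_mask]
        for k in range(1, n_lab + 1):
            cols.append(sgn * maps[:, flat_lab == k].mean(axis=1))
    return np.column_stack(cols) if cols else np.empty((maps.shape[0], 0))


def extract_features(maps_by_step: dict[int, np.ndarray],
                     masks_by_step: dict[int, np.ndarray],
                     clinical: pd.DataFrame,
                     analysis_mask: np.ndarray,
                     label_column: str = "converter") -> FeatureTable:
    """Build the feature table from step maps, significance masks and clinic.

    ``maps_by_step[l]`` is (n_subjects, m); ``masks_by_step[l]`` the 3D
    significant-voxel mask for that step — boolean, or signed int (+1/-1
    direction labels, see ``signed_significance_mask``) in which case
    decrease-cluster features are orientation-flipped.  Step 1 supplies the direct
    features, the largest requested step the indirect ones.  An empty mask
    degrades that step's feature set to nothing (with a warning) — the
    clinical features always remain.
    """
    feats: dict[str, np.ndarray] = {}
    for name in CLINICAL_FEATURES:
        feats[name] = clinical[name].to_numpy(float)
    direct_names: list[str] = []
    indirect_names: list[str] = []
    for l, maps in sorted(maps_by_step.items()):
        sig = masks_by_step[l]
        if not np.asarray(sig, bool).any():
            import warnings
            warnings.warn(f"empty significance mask at step {l}; no SFC features "
                          "from this step (clinical-only fallback)")
            continue
        vals = _cluster_means(np.asarray(maps, float), sig, analysis_mask)
        for k in range(vals.shape[1]):
            name = f"sfc_l{l}_cluster{k + 1}"
            feats[name] = vals[:, k]
            (direct_names if l == 1 else indirect_names).append(name)
    table = pd.DataFrame(feats)
    labels = clinical[label_column].to_numpy(int)
    return FeatureTable(table, labels, list(CLINICAL_FEATURES),
                        direct_names, indirect_names)


def combine_score(table: FeatureTable, which: str | list[str],
                  cv: str | None = None, C: float = 1.0) -> tuple[np.ndarray, bool]:
    """Per-subject discriminant score for a feature set.

    Single-feature sets pass the raw feature through (any strictly monotone
    transform leaves the ROC unchanged).  Multi-feature sets are combined by
    logistic regression on z-scored features — in sample by default,
    leave-one-out with ``cv='loo'``.  Returns (scores, separable_flag); with
    perfect separation the L2 penalty keeps the score finite and the flag is
    set.
    """
    names = table.set_names(which) if isinstance(which, str) else list(which)
    if not names:
        raise ValueError("feature set is empty")
    y = table.labels
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    X = table.features[names].to_numpy(float)
    if X.shape[1] == 1:
        scores = X[:, 0]
        order = np.argsort(scores)
        sep = bool((np.diff(y[order]) >= 0).all() or (np.diff(y[order]) <= 0).all())
        return scores, sep
    Xz = StandardScaler().fit_transform(X)
    if cv == "loo":
        scores = np.empty(len(y), float)
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            clf = LogisticRegression(C=C, max_iter=1000).fit(Xz[keep], y[keep])
            scores[i] = clf.decision_function(Xz[i:i + 1])[0]
    else:
        clf = LogisticRegression(C=C, max_iter=1000).fit(Xz, y)
        scores = clf.decision_function(Xz)
    thresh = np.sort(scores)
    sep = bool(scores[y == 1].min() > scores[y == 0].max()) if thresh.size else False
    return scores, sep


@dataclass
class RocResult:
    """ROC curve, AUC and bootstrap CI for one feature set."""

    name: str
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    n_boot: int
    separable: bool = False


def _auc_mannwhitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic, ties counted 1/2.

    Identical to the trapezoid area under the empirical ROC curve.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    from scipy.stats import rankdata
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_auc(scores: np.ndarray, labels: np.ndarray, name: str = "",
            n_boot: int = 2000, seed: int | np.random.Generator | None = None,
            separable: bool = False) -> RocResult:
    """Empirical ROC over all thresholds with stratified-bootstrap 95% CI."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = _auc_mannwhitney(scores, labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bi = np.concatenate([rng.choice(pos_idx, n_pos), rng.choice(neg_idx, n_neg)])
        boots[b] = _auc_mannwhitney(scores[bi], labels[bi])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(name=name, scores=scores, labels=labels, fpr=fpr, tpr=tpr,
                     auc=auc, ci_low=float(lo), ci_high=float(hi),
                     n_pos=n_pos, n_neg=n_neg, n_boot=n_boot, separable=separable)


class ConversionModel:
    """Converter-vs-non-converter discrimination across feature sets.

    Wraps :func:`combine_score` and :func:`roc_auc` over the standard feature
    sets (clinical / direct / indirect / sfc / combined); ``fit`` returns a
    results object with one :class:`RocResult` per set and a summary table.
    """

    STANDARD_SETS = ("clinical", "direct", "indirect", "sfc", "combined")

    def __init__(self, table: FeatureTable, cv: str | None = None):
        self.table = table
        self.cv = cv

    def fit(self, sets: tuple[str, ...] | None = None, n_boot: int = 2000,
            seed: int | None = None) -> "ConversionResults":
        rng = np.random.default_rng(seed)
        results: dict[str, RocResult] = {}
        for which in sets or self.STANDARD_SETS:
            if not self.table.set_names(which):
                continue
            scores, sep = combine_score(self.table, which, cv=self.cv)
            results[which] = roc_auc(scores, self.table.labels, name=which,
                                     n_boot=n_boot, seed=rng, separable=sep)
        return ConversionResults(self, results)


class ConversionResults:
    def __init__(self, model: ConversionModel, results: dict[str, RocResult]):
        self.model = model
        self.results = results

    def __getitem__(self, which: str) -> RocResult:
        return self.results[which]

    def auc_table(self) -> pd.DataFrame:
        rows = [{"feature_set": r.name, "auc": r.auc, "ci95_low": r.ci_low,
                 "ci95_high": r.ci_high, "n_pos": r.n_pos, "n_neg": r.n_neg,
                 "separable": r.separable}
                for r in self.results.values()]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.auc_table()
        head = (f"Conversion ROC analysis ({self.results[next(iter(self.results))].n_pos}"
                f" converters vs {self.results[next(iter(self.results))].n_neg}"
                " non-converters)")
        return head + "\n" + tab.to_string(index=False, float_format="%.3f")

    def plot(self, path: str | None = None):
        """ROC curves for every fitted feature set (one axes)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for r in self.results.values():
            ax.plot(r.fpr, r.tpr, label=f"{r.name} (AUC={r.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
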