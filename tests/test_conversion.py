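"""ROC/AUC machinery for conversion prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stepconn import conversion as cv


def auc_pair_counting(scores, labels):
    """Brute-force concordant-pair oracle with ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.75])
        labels = np.array([1, 1, 1, 0, 0])
        # 6 pairs, 5 concordant
        assert cv._auc_mannwhitney(scores, labels) == pytest.approx(5 / 6)

    def test_equals_pair_counting_exhaustively(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 4, n).astype(float)  # force ties
            assert cv._auc_mannwhitney(scores, labels) == pytest.approx(
                auc_pair_counting(scores, labels))

    def test_perfect_separation(self):
        res = cv.roc_auc(np.array([3, 4, 5, 0, 1, 2.0]),
                         np.array([1, 1, 1, 0, 0, 0]), n_boot=50, seed=0)
        assert res.auc == 1.0
        assert res.fpr[0] == 0 and res.tpr[-1] == 1

    def test_shuffled_labels_near_half(self, rng):
        scores = rng.standard_normal(2000)
        labels = rng.integers(0, 2, 2000)
        res = cv.roc_auc(scores, labels, n_boot=10, seed=0)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            cv.roc_auc(np.arange(4.0), np.ones(4, int))

    def test_binormal_closed_form_within_bootstrap_ci(self, rng):
        d = 1.0
        scores = np.concatenate([rng.normal(d, 1, 100), rng.normal(0, 1, 100)])
        labels = np.array([1] * 100 + [0] * 100)
        res = cv.roc_auc(scores, labels, n_boot=2000, seed=3)
        theory = stats.norm.cdf(d / np.sqrt(2))
        assert res.ci_low < theory < res.ci_high


def make_table(rng, n=40, d_sfc=2.0, d_clin=0.5):
    labels = np.array([1] * (n // 2) + [0] * (n // 2))
    df = pd.DataFrame({
        "HY": rng.normal(1.5 + d_clin * labels, 1.0),
        "UPDRS_total": rng.normal(30 + 5 * d_clin * labels, 10.0),
        "FOGQ": rng.normal(1.5 + d_clin * labels, 1.0),
        "sfc_l1_cluster1": rng.normal(d_sfc * labels, 1.0),
        "sfc_l4_cluster1": rng.normal(d_sfc * labels, 1.0),
    })
    return cv.FeatureTable(df, labels, ["HY", "UPDRS_total", "FOGQ"],
                           ["sfc_l1_cluster1"], ["sfc_l4_cluster1"])


class TestCombineScore:
    def test_single_feature_monotone_invariance(self, rng):
        table = make_table(rng)
        s1, _ = cv.combine_score(table, "direct")
        res1 = cv.roc_auc(s1, table.labels, n_boot=10, seed=0)
        table2 = table.features.copy()
        table2["sfc_l1_cluster1"] = np.exp(table2["sfc_l1_cluster1"])
        t2 = cv.FeatureTable(table2, table.labels, table.clinical_names,
                             table.direct_names, table.indirect_names)
        s2, _ = cv.combine_score(t2, "direct")
        res2 = cv.roc_auc(s2, t2.labels, n_boot=10, seed=0)
        assert res1.auc == pytest.approx(res2.auc)

    def test_duplicated_feature_same_auc_as_single(self, rng):
        table = make_table(rng)
        dup = table.features.copy()
        dup["sfc_l4_cluster1"] = dup["sfc_l1_cluster1"]
        t2 = cv.FeatureTable(dup, table.labels, table.clinical_names,
                             ["sfc_l1_cluster1"], ["sfc_l4_cluster1"])
        s_single, _ = cv.combine_score(t2, "direct")
        s_both, _ = cv.combine_score(t2, "sfc")
        a1 = cv._auc_mannwhitney(s_single, t2.labels)
        a2 = cv._auc_mannwhitney(s_both, t2.labels)
        assert a1 == pytest.approx(a2, abs=1e-6)

    def test_independent_features_combine_better(self, rng):
        # two independent features each ~AUC 0.7: the combination beats both
        n = 400
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        d = 0.74  # single-feature AUC = Phi(d/sqrt(2)) ~ 0.70
        df = pd.DataFrame({
            "HY": rng.normal(0, 1, n), "UPDRS_total": rng.normal(0, 1, n),
            "FOGQ": rng.normal(0, 1, n),
            "f1": rng.normal(d * labels, 1.0), "f2": rng.normal(d * labels, 1.0),
        })
        table = cv.FeatureTable(df, labels, ["HY", "UPDRS_total", "FOGQ"],
                                ["f1"], ["f2"])
        a1 = cv._auc_mannwhitney(cv.combine_score(table, "direct")[0], labels)
        a2 = cv._auc_mannwhitney(cv.combine_score(table, "indirect")[0], labels)
        both = cv._auc_mannwhitney(cv.combine_score(table, "sfc")[0], labels)
        assert both > max(a1, a2)

    def test_perfect_separation_flagged_but_finite(self, rng):
        labels = np.array([1] * 5 + [0] * 5)
        df = pd.DataFrame({
            "HY": np.arange(10.0), "UPDRS_total": rng.normal(30, 5, 10),
            "FOGQ": rng.normal(2, 1, 10),
            "a": labels * 10.0 + rng.normal(0, 0.1, 10),
            "b": labels * 8.0 + rng.normal(0, 0.1, 10),
        })
        table = cv.FeatureTable(df, labels, ["HY", "UPDRS_total", "FOGQ"],
                                ["a"], ["b"])
        scores, sep = cv.combine_score(table, "sfc")
        assert sep and np.isfinite(scores).all()

    def test_too_few_subjects_per_class_rejected(self, rng):
        table = make_table(rng, n=40)
        t2 = cv.FeatureTable(table.features.iloc[[0, 20, 21, 22]],
                             table.labels[[0, 20, 21, 22]],
                             table.clinical_names, table.direct_names,
                             table.indirect_names)
        with pytest.raises(ValueError, match="2 subjects per class"):
            cv.combine_score(t2, "sfc")


class TestExtractFeatures:
    def _clinical(self, n):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "HY": rng.uniform(0, 3, n), "UPDRS_total": rng.uniform(10, 50, n),
            "FOGQ": rng.uniform(0, 5, n), "converter": [1] * (n // 2) + [0] * (n // 2),
        })

    def test_single_voxel_mask_returns_that_voxel(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        m = int(mask.sum())
        maps = np.arange(6 * m, dtype=float).reshape(6, m)
        sig = np.zeros((4, 4, 4), bool)
        vox = tuple(np.argwhere(mask)[7])
        sig[vox] = True
        table = cv.extract_features({1: maps}, {1: sig}, self._clinical(6), mask)
        assert np.allclose(table.features["sfc_l1_cluster1"], maps[:, 7])

    def test_uniform_map_gives_constant_feature(self):
        mask = np.ones((3, 3, 3), bool)
        maps = np.full((4, 27), 2.5)
        sig = np.zeros((3, 3, 3), bool)
        sig[1, :, :] = True
        table = cv.extract_features({1: maps}, {1: sig}, self._clinical(4), mask)
        assert np.allclose(table.features["sfc_l1_cluster1"], 2.5)

    def test_empty_mask_degrades_to_clinical_with_warning(self):
        mask = np.ones((3, 3, 3), bool)
        maps = np.zeros((4, 27))
        with pytest.warns(UserWarning, match="clinical-only"):
            table = cv.extract_features({1: maps}, {1: np.zeros((3, 3, 3), bool)},
                                        self._clinical(4), mask)
        assert table.direct_names == [] and len(table.clinical_names) == 3

    def test_signed_mask_orients_decrease_clusters(self):
        mask = np.ones((4, 4, 4), bool)
        rng = np.random.default_rng(1)
        labels = np.array([1, 1, 0, 0])
        maps = rng.standard_normal((4, 64))
        maps[labels == 1, :8] -= 3.0  # converters LOWER in this region
        sig = np.zeros((4, 4, 4), np.int8)
        sig[np.unravel_index(np.arange(8), (4, 4, 4))] = -1
        clin = self._clinical(4)
        table = cv.extract_features({4: maps}, {4: sig}, clin, mask)
        feat = table.features[table.indirect_names[0]].to_numpy()
        assert feat[labels == 1].mean() > feat[labels == 0].mean()
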