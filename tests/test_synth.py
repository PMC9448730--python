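"""The synthetic cohort generator: determinism, planted structure, calibration."""

import numpy as np
import pytest
from scipy import stats

import stepconn as sc
from stepconn import preprocess as pp
from stepconn.synth import CONVERTER_GROUP_SIZES, SubjectSpec


class TestBlueprint:
    def test_chain_distances_forced_by_topology(self):
        bp = sc.make_blueprint((8, 8, 8), 4, True, w_in=0.8, w_between=0.4, seed=0)
        assert bp.graph_distances() == {"seed": 0, "c1": 1, "c2": 2, "c3": 3}

    def test_single_community_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sc.make_blueprint(n_communities=1)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            sc.make_blueprint(grid_shape=(2, 2, 2), n_communities=8)

    def test_same_seed_identical_blueprints(self):
        a = sc.make_blueprint(seed=3)
        b = sc.make_blueprint(seed=3)
        assert np.array_equal(a.mask, b.mask)
        assert all(np.array_equal(a.communities[k], b.communities[k])
                   for k in a.communities)

    def test_communities_disjoint_in_mask(self, default_blueprint):
        bp = default_blueprint
        all_idx = np.concatenate(list(bp.communities.values()))
        assert len(np.unique(all_idx)) == len(all_idx)
        assert all_idx.max() < bp.n_voxels

    def test_weight_preconditions(self):
        with pytest.raises(ValueError):
            sc.make_blueprint(w_in=0.5, w_between=0.6)
        with pytest.raises(ValueError):
            sc.make_blueprint(w_in=1.4)


class TestSimulateSubject:
    def test_zero_noise_within_community_correlation_is_one(self):
        bp = sc.make_blueprint(grid_shape=(8, 8, 8), noise_sd=0.0, seed=0)
        ts, _ = sc.simulate_subject(bp, None, seed=0)
        v = bp.communities["seed"][:2]
        r = np.corrcoef(ts.data[v])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_independent_components_near_zero_correlation(self):
        # white-noise config: sample r should behave like the Fisher null
        bp = sc.make_blueprint(grid_shape=(8, 8, 8), w_between=0.0,
                               band_limit=False, seed=0)
        n = bp.n_volumes
        i, j = bp.communities["seed"][0], bp.communities["c2"][0]
        bad = 0
        for s in range(100):
            ts, _ = sc.simulate_subject(bp, None, seed=s)
            r = np.corrcoef(ts.data[[i, j]])[0, 1]
            bad += abs(r) >= 3.0 / np.sqrt(n)
        assert bad <= 4  # |r| < 3/sqrt(n) in ~99% of replicates

    def test_injected_spike_appears_in_fd(self, default_blueprint):
        _, motion = sc.simulate_subject(default_blueprint, None, seed=0,
                                        motion_spikes=[(100, 0.6)])
        fd = pp.framewise_displacement(motion)
        assert fd[100] >= 0.6
        base = np.delete(fd, 100)
        assert base.max() < 0.5

    def test_determinism_bit_identical(self, default_blueprint):
        a, ma = sc.simulate_subject(default_blueprint, None, seed=9)
        b, mb = sc.simulate_subject(default_blueprint, None, seed=9)
        assert np.array_equal(a.data, b.data) and np.array_equal(ma, mb)

    def test_within_correlation_monotone_in_w_in(self):
        means = []
        for w_in in (0.5, 0.7, 0.9):
            bp = sc.make_blueprint(grid_shape=(8, 8, 8), w_in=w_in,
                                   w_between=0.3, seed=0)
            ts, _ = sc.simulate_subject(bp, None, seed=2)
            v = bp.communities["seed"]
            r = np.corrcoef(ts.data[v])
            means.append(r[np.triu_indices(len(v), 1)].mean())
        assert means[0] < means[1] < means[2]

    def test_fisher_null_calibration_ks(self):
        # >= 200 null subjects: z between independent communities ~ N(0, 1/(n-3))
        bp = sc.make_blueprint(grid_shape=(6, 6, 6), w_between=0.0,
                               band_limit=False, seed=0)
        i, j = bp.communities["seed"][0], bp.communities["c3"][0]
        zs = []
        for s in range(220):
            ts, _ = sc.simulate_subject(bp, None, seed=s)
            zs.append(np.arctanh(np.corrcoef(ts.data[[i, j]])[0, 1]))
        sd = 1.0 / np.sqrt(bp.n_volumes - 3)
        p = stats.kstest(np.array(zs), lambda x: stats.norm.cdf(x, 0, sd)).pvalue
        assert p > 0.01


class TestSubjectSpec:
    def test_clinical_score_bounds(self):
        with pytest.raises(ValueError, match="Hoehn"):
            SubjectSpec("s", "PD_TD", 60, "F", clinical={"HY": 5.5})
        with pytest.raises(ValueError, match="nonnegative"):
            SubjectSpec("s", "PD_TD", 60, "F", clinical={"FOGQ": -1.0})

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            SubjectSpec("s", "XX", 60, "F")


class TestSimulateCohort:
    def test_null_cohort_has_zero_effect_size(self, small_blueprint):
        _, _, truth = sc.simulate_cohort(small_blueprint, {"HC": 3}, seed=0)
        assert truth.effect_size == 0.0
        assert not truth.planted_mask.any()

    def test_planted_mask_covers_modulated_community(self, small_blueprint):
        bp = small_blueprint
        _, _, truth = sc.simulate_cohort(
            bp, {"PD_TD": 3, "HC": 3},
            planted_effect={"community": "c2", "multiplier": 2.0, "group": "PD_TD"},
            seed=0)
        coords = bp.voxel_coords()[bp.communities["c2"]]
        assert truth.planted_mask[tuple(coords.T)].all()
        assert truth.distances["c2"] == 2

    def test_group_sizes_and_determinism(self, small_blueprint):
        specs, series, _ = sc.simulate_cohort(small_blueprint,
                                              {"cPD_TD": 2, "ncPD_TD": 3}, seed=5)
        assert [s.group for s in specs] == ["cPD_TD"] * 2 + ["ncPD_TD"] * 3
        specs2, series2, _ = sc.simulate_cohort(small_blueprint,
                                                {"cPD_TD": 2, "ncPD_TD": 3}, seed=5)
        assert all(np.array_equal(a.data, b.data) for a, b in zip(series, series2))
        assert [s.clinical for s in specs] == [s.clinical for s in specs2]

    def test_planted_multiplier_scales_fisher_z(self, small_blueprint):
        bp = small_blueprint
        r0 = bp.expected_r("c1", "c2")
        r1 = bp.expected_r("c1", "c2", {"c2": 1.2})
        assert np.arctanh(r1) / np.arctanh(r0) == pytest.approx(1.2, abs=1e-9)

    def test_clinical_separation_gives_binormal_auc(self):
        # FOGQ alone at separation d: theoretical AUC = Phi(d / sqrt(2));
        # large n so the empirical estimate is tight (clipping at 0 makes it
        # slightly conservative, hence the loose absolute tolerance)
        bp = sc.make_blueprint(grid_shape=(6, 6, 6), n_volumes=50, seed=0)
        d = 1.5
        specs, _, _ = sc.simulate_cohort(bp, {"cPD_TD": 150, "ncPD_TD": 150},
                                         clinical_separation=d, seed=21)
        fogq = np.array([s.clinical["FOGQ"] for s in specs])
        lab = np.array([1] * 150 + [0] * 150)
        from stepconn.conversion import _auc_mannwhitney
        auc = _auc_mannwhitney(fogq, lab)
        assert auc == pytest.approx(stats.norm.cdf(d / np.sqrt(2)), abs=0.06)

    def test_invalid_inputs_rejected(self, small_blueprint):
        with pytest.raises(ValueError, match="positive"):
            sc.simulate_cohort(small_blueprint, {"HC": 0})
        with pytest.raises(ValueError, match="multiplier"):
            sc.simulate_cohort(small_blueprint, {"HC": 2},
                               planted_effect={"community": "c1", "multiplier": 0.0})
        with pytest.raises(ValueError, match="unknown community"):
            sc.simulate_cohort(small_blueprint, {"HC": 2},
                               planted_effect={"community": "zz", "multiplier": 2.0})


class TestCohortIO:
    def test_roundtrip_on_disk(self, tmp_path, small_blueprint):
        from stepconn import io

        specs, series, motions, truth = sc.simulate_cohort(
            small_blueprint, {"HC": 2}, seed=0, return_motion=True)
        out = sc.synth.write_cohort(tmp_path, small_blueprint, specs, series,
                                    motions, truth)
        data, _, tr = io.load_bold(out / "sub-000_bold.nii")
        mask, _ = io.load_mask(out / "mask.nii")
        assert tr == pytest.approx(3.0)
        assert np.allclose(data[mask], series[0].data, atol=1e-5)
        params = io.load_motion(out / "rp_sub-000.txt")
        assert np.allclose(params, motions[0], atol=1e-7)
        table = io.load_cohort(out / "cohort.csv")
        assert list(table["subject_id"]) == ["sub-000", "sub-001"]
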