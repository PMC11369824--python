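"""Functional connectivity, group statistics, graphs and the
brain-behaviour regression, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cppfmri as cf
from cppfmri.connectivity import (fc_matrix, node_strength, pair_names,
                                  paired_fc_test, seed_corr_map,
                                  group_seed_ttest, cluster_level_correct,
                                  mean_seed_fc, strength_compare,
                                  export_graph, fc_behaviour_regression)
from cppfmri.glm import StatMap
from conftest import make_fc


def ts(data, names, subject="s1", condition="rest_pre"):
    return cf.RoiTimeseries(np.asarray(data, dtype=float), list(names),
                            subject, condition)


class TestRoiTimeseries:
    def test_constant_roi_gives_constant_series(self, small_atlas):
        data = np.zeros((*small_atlas.labels.shape, 5))
        data[small_atlas.mask("ROI01")] = 3.0
        run = cf.BoldRun(data=data, tr_s=2.0, voxel_mm=small_atlas.voxel_mm,
                         affine=small_atlas.affine)
        out = cf.roi_timeseries(run, small_atlas)
        np.testing.assert_allclose(out.data[:, 0], 3.0)

    def test_two_voxel_roi_is_their_mean(self):
        labels = np.zeros((4, 4, 2), dtype=int)
        labels[0, 0, 0] = labels[1, 1, 1] = 1
        atlas = cf.RoiAtlas(labels=labels, name_map={1: "A"},
                            voxel_mm=(1, 1, 1))
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 4, 2, 7))
        run = cf.BoldRun(data=data, tr_s=2.0, voxel_mm=(1, 1, 1),
                         affine=np.eye(4))
        out = cf.roi_timeseries(run, atlas)
        oracle = (data[0, 0, 0] + data[1, 1, 1]) / 2.0
        np.testing.assert_allclose(out.data[:, 0], oracle, atol=1e-12)

    def test_ten_roi_atlas_gives_ten_named_columns(self, full_atlas, rng):
        data = rng.normal(100, 1, (*full_atlas.labels.shape, 10))
        run = cf.BoldRun(data=data, tr_s=2.0, voxel_mm=full_atlas.voxel_mm,
                         affine=full_atlas.affine)
        out = cf.roi_timeseries(run, full_atlas)
        assert out.data.shape[1] == 10
        assert out.roi_names == list(cf.DEFAULT_ROI_NAMES)

    def test_grid_mismatch_rejected(self, small_atlas, rng):
        run = cf.BoldRun(data=rng.normal(size=(4, 4, 2, 5)), tr_s=2.0,
                         voxel_mm=(1, 1, 1), affine=np.eye(4))
        with pytest.raises(ValueError, match="grid"):
            cf.roi_timeseries(run, small_atlas)


class TestFcMatrix:
    def test_duplicated_column_correlates_at_clip(self, rng):
        x = rng.normal(size=20)
        fc = fc_matrix(ts(np.column_stack([x, x]), ["A", "B"]))
        assert fc.r[0, 1] == pytest.approx(1.0)
        assert fc.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_negated_column_gives_minus_one(self, rng):
        x = rng.normal(size=20)
        fc = fc_matrix(ts(np.column_stack([x, -x]), ["A", "B"]))
        assert fc.r[0, 1] == pytest.approx(-1.0)

    def test_ten_rois_have_45_pairs(self, rng):
        names = list(cf.DEFAULT_ROI_NAMES)
        fc = fc_matrix(ts(rng.normal(size=(50, 10)), names))
        assert len(pair_names(names)) == 45
        assert fc.pair_values().size == 45

    def test_diagonal_z_excluded(self, rng):
        fc = fc_matrix(ts(rng.normal(size=(30, 3)), list("ABC")))
        assert np.isnan(np.diag(fc.z)).all()
        assert np.allclose(np.diag(fc.r), 1.0)

    def test_symmetry_and_monotone_z(self, rng):
        fc = fc_matrix(ts(rng.normal(size=(40, 5)), list("ABCDE")))
        np.testing.assert_allclose(fc.r, fc.r.T, atol=1e-12)
        iu = np.triu_indices(5, 1)
        order_r = np.argsort(fc.r[iu])
        order_z = np.argsort(fc.z[iu])
        assert np.array_equal(order_r, order_z)

    def test_zero_variance_column_named(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 5.0
        with pytest.raises(ValueError, match="B"):
            fc_matrix(ts(X, list("ABC")))

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="8 frames"):
            fc_matrix(ts(rng.normal(size=(5, 3)), list("ABC")))


class TestPairedFcTest:
    names = list("ABCD")

    def _cohort(self, rng, n=12, shift=0.0, pair_idx=0):
        a, b = [], []
        for s in range(n):
            base = rng.normal(0.2, 0.1, 6)
            zb = base.copy()
            za = base + rng.normal(0, 0.05, 6)
            za[pair_idx] += shift
            a.append(make_fc(za, self.names, subject=f"s{s}", condition="post"))
            b.append(make_fc(zb, self.names, subject=f"s{s}", condition="pre"))
        return a, b

    def test_df_is_n_minus_one(self, rng):
        a, b = self._cohort(rng, n=12)
        res = paired_fc_test(a, b)
        assert (res.table["df"] == 11).all()

    def test_identical_conditions_give_t0_p1(self, rng):
        a, _ = self._cohort(rng)
        res = paired_fc_test(a, a)
        np.testing.assert_allclose(res.table["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["p_raw"], 1.0)

    def test_adjusted_p_never_below_raw(self, rng):
        a, b = self._cohort(rng, shift=0.2)
        res = paired_fc_test(a, b)
        assert (res.table["p_adj"] >= res.table["p_raw"] - 1e-15).all()

    def test_matches_scipy_oracle_per_pair(self, rng):
        a, b = self._cohort(rng, shift=0.15, pair_idx=2)
        res = paired_fc_test(a, b)
        za = np.stack([m.pair_values() for m in a])
        zb = np.stack([m.pair_values() for m in b])
        t2, p2 = stats.ttest_rel(za[:, 2], zb[:, 2])
        assert res.table["t"].iloc[2] == pytest.approx(t2)
        assert res.table["p_raw"].iloc[2] == pytest.approx(p2)

    def test_planted_shift_detected_in_seeded_replicates(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            a, b = self._cohort(rng, n=12, shift=0.4, pair_idx=3)
            res = paired_fc_test(a, b, q=0.05)
            if res.table["significant"].iloc[3]:
                hits += 1
        assert hits >= 0.95 * reps

    def test_subject_mismatch_rejected(self, rng):
        a, b = self._cohort(rng)
        b[0].subject = "other"
        with pytest.raises(ValueError, match="mismatch"):
            paired_fc_test(a, b)


class TestSeedMaps:
    def _run(self, rng, shape=(10, 10, 5), n=60):
        data = rng.normal(100, 1, (*shape, n))
        return cf.BoldRun(data=data, tr_s=2.0, voxel_mm=(1, 1, 1),
                          affine=np.eye(4))

    def test_own_series_maps_at_clip(self, rng):
        run = self._run(rng)
        mask = np.ones(run.shape3d, dtype=bool)
        sm = seed_corr_map(run, run.data[3, 4, 2], mask)
        assert sm.z[3, 4, 2] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_independent_seed_gives_null_z(self, rng):
        n = 120
        run = self._run(rng, n=n)
        seed = rng.normal(size=n)
        sm = seed_corr_map(run, seed, np.ones(run.shape3d, dtype=bool))
        se = 1.0 / np.sqrt(n - 3)
        frac = np.mean(np.abs(sm.z[np.isfinite(sm.z)]) < 2 * se)
        assert frac > 0.90   # ~95% expected within 2 SE

    def test_coupled_roi_exceeds_outside_median(self, small_atlas):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.7
        run, _ = cf.gen_rest_bold(small_atlas, cf.CovSpec(m), 200, seed=8)
        seed_series = cf.roi_timeseries(run, small_atlas).data[:, 0]
        brain = np.ones(run.shape3d, dtype=bool)
        sm = seed_corr_map(run, seed_series, brain, seed="ROI01")
        inside = sm.z[small_atlas.mask("ROI02")]
        outside = sm.z[small_atlas.labels == 0]
        assert inside.mean() > np.median(outside)

    def test_zero_variance_seed_rejected(self, rng):
        run = self._run(rng)
        with pytest.raises(ValueError, match="zero-variance"):
            seed_corr_map(run, np.ones(run.n_frames),
                          np.ones(run.shape3d, dtype=bool))

    def test_group_ttest_identical_gives_zero(self, rng):
        run = self._run(rng)
        mask = np.ones(run.shape3d, dtype=bool)
        maps = [seed_corr_map(run, rng.normal(size=run.n_frames), mask,
                              subject=f"s{i}") for i in range(4)]
        out = group_seed_ttest(maps, maps)
        np.testing.assert_allclose(np.nan_to_num(out.volume("stat")), 0.0,
                                   atol=1e-10)
        assert out.df == 3

    def test_group_ttest_swap_flips_sign(self, rng):
        mask = np.ones((6, 6, 3), dtype=bool)
        def mk(i):
            r = self._run(rng, shape=(6, 6, 3), n=40)
            return seed_corr_map(r, rng.normal(size=40), mask,
                                 subject=f"s{i}")
        a = [mk(i) for i in range(4)]
        b = [mk(i) for i in range(4)]
        for m, m2 in zip(a, b):
            m2.subject = m.subject
        ab = group_seed_ttest(a, b).volume("stat")
        ba = group_seed_ttest(b, a).volume("stat")
        np.testing.assert_allclose(ab, -ba, atol=1e-10, equal_nan=True)


class TestClusterLevelCorrect:
    def _map(self, vol, df=11):
        p = 2 * stats.t.sf(np.abs(vol.ravel()), df)
        return StatMap(vol.ravel(), p, df, shape3d=vol.shape,
                       voxel_mm=np.ones(3))

    def test_extent_logic_keeps_blob_drops_singletons(self):
        vol = np.zeros((16, 16, 8))
        vol[2:8, 2:8, 2:5] = 8.0          # large planted effect
        vol[12, 12, 6] = 8.0              # isolated suprathreshold voxel
        sm = self._map(vol)
        out, cs = cluster_level_correct(sm, n_null=150, seed=0,
                                        brain_mask=np.ones(vol.shape, bool))
        assert cs.n_clusters == 1
        assert cs.sizes[0] == 6 * 6 * 3
        assert out.volume("stat")[12, 12, 6] == 0.0

    def test_deterministic_given_seed(self, rng):
        vol = rng.normal(size=(12, 12, 6)) * 2.0
        sm = self._map(vol)
        mask = np.ones(vol.shape, bool)
        _, cs1 = cluster_level_correct(sm, n_null=120, seed=5, brain_mask=mask)
        _, cs2 = cluster_level_correct(sm, n_null=120, seed=5, brain_mask=mask)
        assert np.array_equal(cs1.labels, cs2.labels)

    def test_small_null_rejected(self, rng):
        sm = self._map(np.zeros((8, 8, 4)))
        with pytest.raises(ValueError, match="100"):
            cluster_level_correct(sm, n_null=50, seed=0)


class TestMeanSeedFc:
    def _map(self, z):
        return cf.SeedMap(z=z, seed="A")

    def test_uniform_map(self):
        z = np.full((6, 6, 3), 0.3)
        assert mean_seed_fc(self._map(z), np.ones(z.shape, bool)) == \
            pytest.approx(0.3)

    def test_two_halves_average(self):
        z = np.full((6, 6, 2), 0.2)
        z[3:] = 0.4
        assert mean_seed_fc(self._map(z), np.ones(z.shape, bool)) == \
            pytest.approx(0.3)

    def test_equals_brute_force_and_excludes_seed(self, rng):
        z = rng.normal(size=(6, 6, 3))
        mask = rng.random(z.shape) > 0.3
        seed_mask = np.zeros(z.shape, bool)
        seed_mask[0:2, 0:2, 0] = True
        got = mean_seed_fc(self._map(z), mask, seed_mask)
        oracle = z[mask & ~seed_mask].mean()
        assert got == pytest.approx(oracle)

    def test_empty_after_exclusion_rejected(self):
        z = np.zeros((2, 2, 1))
        with pytest.raises(ValueError, match="empty"):
            mean_seed_fc(self._map(z), np.ones(z.shape, bool),
                         np.ones(z.shape, bool))


class TestNodeStrength:
    def test_hand_summation(self):
        fc = make_fc([0.5, 0.2, -0.1], list("ABC"))
        s = node_strength(fc)
        np.testing.assert_allclose(s.to_numpy(), [0.7, 0.4, 0.1])

    def test_all_zero(self):
        fc = make_fc([0.0, 0.0, 0.0], list("ABC"))
        assert (node_strength(fc) == 0).all()

    def test_permutation_equivariance(self, rng):
        z = rng.normal(0, 0.3, 6)
        fc = make_fc(z, list("ABCD"))
        s = node_strength(fc)
        perm = [2, 0, 3, 1]
        zperm = np.full((4, 4), np.nan)
        for i in range(4):
            for j in range(4):
                if i != j:
                    zperm[i, j] = fc.z[perm[i], perm[j]]
        fc2 = cf.FcMatrix(np.tanh(np.nan_to_num(zperm)), zperm,
                          [fc.roi_names[i] for i in perm])
        s2 = node_strength(fc2)
        for i, name in enumerate(fc2.roi_names):
            assert s2[name] == pytest.approx(s[name])

    def test_abs_mode_sums_magnitudes(self):
        fc = make_fc([0.5, 0.2, -0.1], list("ABC"))
        np.testing.assert_allclose(node_strength(fc, use_abs=True).to_numpy(),
                                   [0.7, 0.6, 0.3])

    def test_asymmetric_matrix_rejected(self):
        fc = make_fc([0.5, 0.2, -0.1], list("ABC"))
        fc.z[0, 1] = 0.9
        with pytest.raises(ValueError, match="asymmetric"):
            node_strength(fc)

    def test_strength_compare_identical_gives_zero_df_n_minus_1(self, rng):
        s = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("ABCD"),
                         index=[f"s{i}" for i in range(12)])
        res = strength_compare(s, s)
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-12)
        assert (res["df"] == 11).all()


class TestExportGraph:
    def test_threshold_boundary_and_node_count(self, tmp_path, full_atlas,
                                               rng):
        k = 10
        z = np.zeros((k, k))
        z[0, 1] = z[1, 0] = 0.15
        z[2, 3] = z[3, 2] = 0.25
        names = full_atlas.roi_names
        export_graph(z, names, full_atlas.coords_mm, rng.normal(size=k), 0.2,
                     tmp_path / "g.node", tmp_path / "g.edge")
        edges = np.loadtxt(tmp_path / "g.edge")
        assert edges[0, 1] == 0.0 and edges[2, 3] == 0.25
        nodes = (tmp_path / "g.node").read_text().strip().splitlines()
        assert len(nodes) == 10
        assert nodes[0].split("\t")[-1] == "ACo"

    def test_zero_threshold_preserves_matrix(self, tmp_path, full_atlas, rng):
        z = rng.normal(0, 0.3, (10, 10))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        export_graph(z, full_atlas.roi_names, full_atlas.coords_mm,
                     np.ones(10), 0.0, tmp_path / "g.node",
                     tmp_path / "g.edge")
        back = np.loadtxt(tmp_path / "g.edge")
        np.testing.assert_allclose(back, z, atol=1e-5)


class TestFcBehaviourRegression:
    def _table(self, x, y, pair="A-B", cond="rest_pre"):
        return pd.DataFrame({
            "subject": [f"s{i}" for i in range(len(x))],
            "condition": cond, "pair": pair, "cpp_delta_s": x, "z": y,
        })

    def test_exact_linear_relation_gives_r2_one(self):
        x = np.arange(8, dtype=float)
        res = fc_behaviour_regression(self._table(x, 0.01 * x + 0.2))
        assert res["r_squared"].iloc[0] == pytest.approx(1.0)
        assert res["slope"].iloc[0] == pytest.approx(0.01)

    def test_four_point_hand_oracle(self):
        # textbook formula: r = cov(x,y) / (sx sy)
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([0.1, 0.25, 0.2, 0.45])
        res = fc_behaviour_regression(self._table(x, y))
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        assert res["pearson_r"].iloc[0] == pytest.approx(r_oracle)
        assert res["r_squared"].iloc[0] == pytest.approx(r_oracle ** 2)

    def test_adjusted_p_within_condition(self, rng):
        frames = []
        for pair in ("A-B", "A-C", "B-C"):
            frames.append(self._table(rng.normal(size=10),
                                      rng.normal(size=10), pair=pair))
        res = fc_behaviour_regression(pd.concat(frames, ignore_index=True))
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()
        assert len(res) == 3

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fc_behaviour_regression(self._table(np.ones(5),
                                                np.arange(5.0)))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            fc_behaviour_regression(self._table(np.arange(2.0),
                                                np.arange(2.0)))
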