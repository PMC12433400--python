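import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from rmtbi.connectivity import (
    ConnectivityMatrix,
    cluster_nodes,
    compare_degree_by_region,
    degree_table,
    group_edge_z,
    n_unique_pairs,
    network_metrics,
    pearson_fisher_matrix,
    preprocess_timeseries,
    threshold_binarize,
)
from rmtbi.simulate import SimulationConfig, make_phantom_atlas, simulate_bold_study


def brute_force_metrics(a):
    """Adjacency enumeration + Floyd-Warshall oracle for small graphs."""
    n = a.shape[0]
    edges = sum(a[i, j] > 0 for i in range(n) for j in range(i + 1, n))
    degree = [sum(a[i, j] > 0 for j in range(n) if j != i) for i in range(n)]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j] > 0:
                dist[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    finite = dist[(dist > 0) & np.isfinite(dist)]
    apl = finite.mean() if finite.size else None
    return {
        "degree": degree,
        "n_edges": int(edges),
        "density": 2 * edges / (n * (n - 1)),
        "apl": apl,
        "disconnected": int(np.isinf(dist).sum()),
    }


def random_binary(rng, n, p):
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    return ConnectivityMatrix(labels=np.arange(n), values=a, kind="binary")


class TestPreprocess:
    def test_motion_regressor_projected_out(self):
        rng = np.random.default_rng(0)
        motion = rng.standard_normal((200, 1))
        resid = preprocess_timeseries(motion.copy(), tr_s=1.0, nuisance=motion)
        assert np.max(np.abs(resid)) < 1e-9

    def test_passband_and_stopband_gains(self):
        t = np.arange(2000, dtype=float)
        keep = np.sin(2 * np.pi * 0.05 * t)
        kill = np.sin(2 * np.pi * 0.2 * t)
        out_keep = preprocess_timeseries(keep, tr_s=1.0)[500:1500, 0]
        out_kill = preprocess_timeseries(kill, tr_s=1.0)[500:1500, 0]
        assert np.abs(out_keep).max() >= 0.95
        assert np.abs(out_kill).max() <= 0.05

    def test_white_noise_variance_reduced_and_zero_mean(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2000, 3))
        out = preprocess_timeseries(x, tr_s=1.0)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-10)
        # pass band 0.01-0.1 Hz holds ~18% of the white spectrum
        ratio = out.var(axis=0) / x.var(axis=0)
        assert np.all(ratio < 0.3)
        assert np.all(ratio > 0.05)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_timeseries(np.zeros((100, 2)), tr_s=2.0, band_hz=(0.01, 0.3))


class TestPearsonFisher:
    def test_identical_signals_clip_finite(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        r, z = pearson_fisher_matrix(np.column_stack([x, x]))
        assert r.values[0, 1] == pytest.approx(1.0)
        assert np.isfinite(z.values[0, 1])

    def test_fisher_z_closed_form(self):
        # construct two series with exact sample correlation 0.9
        n = 200
        x = np.sin(np.arange(n))
        x = (x - x.mean()) / x.std()
        e = np.cos(np.arange(n) * 1.7)
        e = e - e.mean()
        e -= x * (x @ e) / (x @ x)  # orthogonalize
        e /= e.std()
        y = 0.9 * x + np.sqrt(1 - 0.81) * e
        r, z = pearson_fisher_matrix(np.column_stack([x, y]))
        assert r.values[0, 1] == pytest.approx(0.9, abs=1e-12)
        assert z.values[0, 1] == pytest.approx(1.4722, abs=5e-5)

    def test_pair_count_identity(self):
        assert n_unique_pairs(171) == 14535
        r, _ = pearson_fisher_matrix(
            np.random.default_rng(0).standard_normal((10, 6))
        )
        iu = np.triu_indices(6, 1)
        assert iu[0].size == n_unique_pairs(6)

    def test_constant_signal_row_zeroed(self):
        sig = np.column_stack(
            [np.ones(30), np.random.default_rng(1).standard_normal(30)]
        )
        with pytest.warns(UserWarning, match="constant"):
            r, z = pearson_fisher_matrix(sig)
        assert r.values[0, 1] == 0.0

    @given(st.floats(min_value=-5, max_value=5))
    @settings(deadline=None)
    def test_fisher_z_odd_and_invertible(self, x):
        assert np.tanh(np.arctanh(np.tanh(x))) == pytest.approx(np.tanh(x), abs=1e-12)
        assert np.arctanh(np.tanh(-x)) == pytest.approx(-np.arctanh(np.tanh(x)), abs=1e-9)


class TestGroupEdgeZ:
    def _mats(self, edge_values):
        mats = []
        for v in edge_values:
            m = np.zeros((2, 2))
            m[0, 1] = m[1, 0] = v
            mats.append(ConnectivityMatrix(labels=np.array([1, 2]), values=m, kind="z"))
        return mats

    def test_all_zero_edge(self):
        gz, flagged = group_edge_z(self._mats([0.0, 0.0, 0.0]))
        assert gz.values[0, 1] == 0.0
        assert not flagged.any()

    def test_hand_computed_t_to_normal_deviate(self):
        gz, _ = group_edge_z(self._mats([0.5, 0.6, 0.7, 0.8]))
        # t = 0.65 / (0.1291/2) = 10.0698 on 3 df -> Phi^-1(CDF) = 3.0778
        assert gz.values[0, 1] == pytest.approx(3.0778, abs=5e-4)

    def test_sign_antisymmetry(self):
        pos, _ = group_edge_z(self._mats([0.5, 0.6, 0.7, 0.8]))
        neg, _ = group_edge_z(self._mats([-0.5, -0.6, -0.7, -0.8]))
        assert neg.values[0, 1] == pytest.approx(-pos.values[0, 1], abs=1e-12)

    def test_zero_variance_edge_sentinel(self):
        gz, flagged = group_edge_z(self._mats([0.4, 0.4, 0.4]))
        assert flagged[0, 1]
        assert gz.values[0, 1] == 40.0


class TestThresholdAndMetrics:
    def test_all_subthreshold_empty_graph(self):
        m = ConnectivityMatrix(
            labels=np.arange(4), values=np.full((4, 4), 1.0) - np.eye(4), kind="group_z"
        )
        b = threshold_binarize(m, zthr=2.3)
        metrics = network_metrics(b)
        assert metrics.n_edges == 0
        assert metrics.average_path_length is None

    def test_tie_at_threshold_kept(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 2.3
        m = ConnectivityMatrix(labels=np.arange(3), values=v, kind="group_z")
        assert threshold_binarize(m).values[0, 1] == 1.0

    def test_complete_graph_closed_form(self):
        n = 7
        a = np.ones((n, n)) - np.eye(n)
        metrics = network_metrics(
            ConnectivityMatrix(labels=np.arange(n), values=a, kind="binary")
        )
        assert np.all(metrics.degree == n - 1)
        assert metrics.density == 1.0
        assert metrics.average_path_length == 1.0

    def test_path_graph_enumeration(self):
        a = np.zeros((4, 4))
        for i in range(3):
            a[i, i + 1] = a[i + 1, i] = 1
        metrics = network_metrics(
            ConnectivityMatrix(labels=np.arange(4), values=a, kind="binary")
        )
        assert metrics.degree.tolist() == [1, 2, 2, 1]
        assert metrics.density == pytest.approx(0.5)
        assert metrics.average_path_length == pytest.approx(5 / 3)

    def test_density_from_printed_average_degrees(self):
        # N = 171 reconciles the printed pair count and densities
        assert 20.83 / 170 == pytest.approx(0.123, abs=5e-4)
        assert 12.78 / 170 == pytest.approx(0.075, abs=5e-4)

    def test_metrics_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(5, 31))
            m = random_binary(rng, n, rng.uniform(0.05, 0.6))
            metrics = network_metrics(m)
            oracle = brute_force_metrics(m.values)
            assert metrics.degree.tolist() == oracle["degree"]
            assert metrics.n_edges == oracle["n_edges"]
            assert metrics.density == pytest.approx(oracle["density"])
            if oracle["apl"] is None:
                assert metrics.average_path_length is None
            else:
                assert metrics.average_path_length == pytest.approx(oracle["apl"])

    def test_degree_invariants(self):
        rng = np.random.default_rng(5)
        m = random_binary(rng, 20, 0.3)
        metrics = network_metrics(m)
        assert (metrics.degree <= 19).all()
        assert metrics.degree.sum() == 2 * metrics.n_edges
        table = degree_table(m)
        assert np.allclose(table["degree"], metrics.degree.to_numpy())

    def test_threshold_count_matches_brute_force(self):
        rng = np.random.default_rng(13)
        v = rng.normal(0, 2.0, size=(15, 15))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        m = ConnectivityMatrix(labels=np.arange(15), values=v, kind="group_z")
        b = threshold_binarize(m, zthr=2.3)
        manual = sum(
            abs(v[i, j]) >= 2.3 for i in range(15) for j in range(i + 1, 15)
        )
        assert network_metrics(b).n_edges == manual


class TestClustering:
    def _block_matrix(self, sizes, within=10.0):
        n = sum(sizes)
        v = np.zeros((n, n))
        start = 0
        for s in sizes:
            v[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(v, 0.0)
        return ConnectivityMatrix(labels=np.arange(n), values=v, kind="group_z")

    def test_two_blocks_two_modules(self):
        m = self._block_matrix([5, 5])
        modules = cluster_nodes(m, k=3)
        assert len(set(modules)) == 2
        assert len(set(modules[:5])) == 1 and len(set(modules[5:])) == 1

    def test_complete_knn_single_module(self):
        m = self._block_matrix([4, 4])
        modules = cluster_nodes(m, k=7)
        assert len(set(modules)) == 1

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            cluster_nodes(self._block_matrix([4, 4]), k=0)

    def test_recovers_generator_modules(self):
        # 4-module study: 16 areas in 4 region groups, no group attenuation,
        # all 14 subjects pooled for the group map
        cfg = SimulationConfig(seed=31, n_regions=16, affected_groups_bold=())
        atlas = make_phantom_atlas(cfg)
        four_groups = ("thalamus", "hippocampus", "basal ganglia", "cerebellum")
        regions = atlas.regions.copy()
        tissue = regions["region_group"] != "blood"
        regions.loc[tissue, "region_group"] = [
            four_groups[i % 4] for i in range(int(tissue.sum()))
        ]
        from rmtbi.core import LabelAtlas

        atlas = LabelAtlas(labels=atlas.labels, regions=regions)
        study = simulate_bold_study(cfg, atlas)
        zs = []
        for _, s in study.subjects.iterrows():
            sig = study.signals[s.subject_id]
            resid = preprocess_timeseries(
                sig.to_numpy(), tr_s=1.0, nuisance=study.nuisance[s.subject_id].to_numpy()
            )
            _, z = pearson_fisher_matrix(resid, labels=np.asarray(sig.columns))
            zs.append(z)
        gz, _ = group_edge_z(zs)
        modules = cluster_nodes(gz, k=3)
        truth = (
            study.ground_truth.bold.query("subject_id == 'sham01'")
            .set_index("label_id")
            .loc[np.asarray(zs[0].labels), "module"]
        )
        assert adjusted_rand_score(truth.to_numpy(), modules) >= 0.9


class TestDegreeComparison:
    def _regions(self, n, group="thalamus"):
        return pd.DataFrame(
            {
                "label_id": np.arange(n),
                "region_group": [group] * n,
            }
        )

    def _table(self, degrees):
        return pd.DataFrame(
            {"label_id": np.arange(len(degrees)), "degree": degrees}
        )

    def test_identical_networks_nothing_flagged(self):
        d = self._table([3, 4, 5, 6, 7])
        out, global_res = compare_degree_by_region(d, d, self._regions(5))
        assert not out["flagged"].any()
        assert global_res["p"] == 1.0

    def test_constant_difference_exact_signed_rank(self):
        sham = self._table([5, 6, 7, 8, 9])
        hit = self._table([1, 2, 3, 4, 5])
        out, global_res = compare_degree_by_region(
            sham, hit, self._regions(5), labels=("sham", "impacted")
        )
        row = out.iloc[0]
        # constant paired difference -4: paired t undefined, exact WSR floor
        assert row["test"] == "wilcoxon"
        assert row["p"] == pytest.approx(0.0625)
        assert row["direction"] == "impacted < sham"
        assert global_res["p"] == pytest.approx(0.0625)

    def test_mismatched_nodes_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            compare_degree_by_region(
                self._table([1, 2, 3]),
                pd.DataFrame({"label_id": [7, 8, 9], "degree": [1, 2, 3]}),
                self._regions(3),
            )

    def test_small_region_warned(self):
        regions = pd.DataFrame(
            {"label_id": [0, 1, 2, 3], "region_group": ["a", "a", "a", "b"]}
        )
        d = self._table([1, 2, 3, 4])
        e = self._table([2, 3, 4, 5])
        with pytest.warns(UserWarning, match="'b'"):
            out, _ = compare_degree_by_region(d, e, regions)
        assert set(out["region_group"]) == {"a"}


class TestPipelineRecovery:
    def test_attenuated_groups_have_lower_degree(self):
        """Whole-pipeline: connectivity attenuation in the impacted group
        lowers its global mean degree (single default study)."""
        cfg = SimulationConfig(seed=17)
        atlas = make_phantom_atlas(cfg)
        study = simulate_bold_study(cfg, atlas)
        degrees = {}
        for group in ("sham", "impacted"):
            zs = []
            for _, s in study.subjects.query("group == @group").iterrows():
                sig = study.signals[s.subject_id]
                resid = preprocess_timeseries(
                    sig.to_numpy(),
                    tr_s=cfg.tr_s,
                    nuisance=study.nuisance[s.subject_id].to_numpy(),
                )
                _, z = pearson_fisher_matrix(resid, labels=np.asarray(sig.columns))
                zs.append(z)
            gz, _ = group_edge_z(zs)
            metrics = network_metrics(threshold_binarize(gz))
            degrees[group] = metrics.average_degree
        assert degrees["impacted"] < degrees["sham"]

    def test_attenuated_thalamus_flagged_in_regional_comparison(self):
        cfg = SimulationConfig(seed=19, affected_groups_bold=("thalamus",))
        atlas = make_phantom_atlas(cfg)
        study = simulate_bold_study(cfg, atlas)
        tables = {}
        z_maps = {}
        for group in ("sham", "impacted"):
            zs = []
            for _, s in study.subjects.query("group == @group").iterrows():
                sig = study.signals[s.subject_id]
                resid = preprocess_timeseries(
                    sig.to_numpy(),
                    tr_s=cfg.tr_s,
                    nuisance=study.nuisance[s.subject_id].to_numpy(),
                )
                _, z = pearson_fisher_matrix(resid, labels=np.asarray(sig.columns))
                zs.append(z)
            gz, _ = group_edge_z(zs)
            z_maps[group] = gz
            tables[group] = degree_table(threshold_binarize(gz))
        regions = atlas.regions.query("region_group != 'blood'")
        out, _ = compare_degree_by_region(
            tables["sham"], tables["impacted"], regions, labels=("sham", "impacted")
        )
        thal = out[out["region_group"] == "thalamus"].iloc[0]
        assert thal["mean_degree_impacted"] < thal["mean_degree_sham"]
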