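"""Generator behaviour: trees, niches, sites, communities, masking, presets."""

import numpy as np
import pandas as pd
import pytest

import lineagediv as L
from lineagediv.phylo import PhyloError
from lineagediv.simulate import (SimulationConfig, distance_matrix_km, ech_niche_means,
                                 simulate_niche, simulate_sites)


class TestSimulateTree:
    def test_two_tip_tree(self):
        t = L.simulate_tree(2, 1.0, 0.0, seed=1)
        d = t.tip_depths()
        assert t.n_tips == 2 and d[0] == pytest.approx(d[1])

    def test_binary_node_count(self):
        t = L.simulate_tree(50, 1.0, 0.2, seed=7)
        nodes = sum(1 for _ in t.dendropy_tree.preorder_node_iter())
        edges = sum(1 for nd in t.dendropy_tree.preorder_node_iter()
                    if nd.parent_node is not None)
        assert nodes == 2 * 50 - 1 and edges == 2 * 50 - 2

    def test_deterministic(self):
        a = L.write_newick(L.simulate_tree(50, 1.0, 0.0, seed=7))
        b = L.write_newick(L.simulate_tree(50, 1.0, 0.0, seed=7))
        assert a == b

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            L.simulate_tree(10, 0.5, 0.5, seed=1)
        with pytest.raises(ValueError):
            L.simulate_tree(1, 1.0, 0.0, seed=1)


class TestSimulateNiche:
    def test_zero_variance(self, bd_tree):
        niche = simulate_niche(bd_tree, 0.5, 0.0, 1500.0, seed=1)
        assert all(v == pytest.approx(1500.0) for v in niche.values())

    def test_bm_covariance_at_lambda_one(self):
        """Sample covariance over replicate draws matches shared-path BM cov."""
        t = L.simulate_tree(12, 1.0, 0.0, seed=21)
        c, tips = t.vcv()
        sigma2 = 100.0
        reps = np.vstack([
            np.array([simulate_niche(t, 1.0, sigma2, 5000.0, seed=s)[tp] for tp in tips])
            for s in range(2000)
        ])
        assert reps.min() > 1.0, "no truncation should occur at this mean"
        emp = np.cov(reps.T)
        target = sigma2 * c
        # entrywise within 3 Monte-Carlo standard errors
        mc_se = np.sqrt((target ** 2 + np.outer(np.diag(target), np.diag(target))) / 2000)
        assert (np.abs(emp - target) <= 3.2 * mc_se + 1e-9).all()

    def test_independence_at_lambda_zero(self):
        t = L.simulate_tree(10, 1.0, 0.0, seed=22)
        tips = t.tip_labels
        reps = np.vstack([
            np.array([simulate_niche(t, 0.0, 50.0, 5000.0, seed=1000 + s)[tp] for tp in tips])
            for s in range(2000)
        ])
        r = np.corrcoef(reps.T)
        off = r[~np.eye(len(tips), dtype=bool)]
        # 99% null band for a correlation of 2000 iid draws
        band = 2.576 / np.sqrt(2000)
        assert (np.abs(off) < band * 1.6).all()

    def test_non_ultrametric_rejected(self):
        bad = L.read_newick("((A:1,B:2):1,C:5);")
        with pytest.raises(PhyloError, match="ultrametric"):
            simulate_niche(bad, 0.5, 10.0, 1000.0, seed=0)


class TestSimulateSites:
    def test_range_and_shape(self):
        s = simulate_sites(10, (300.0, 3500.0), 200.0, seed=3)
        assert len(s) == 10
        assert s["map_mm"].min() >= 300.0 and s["map_mm"].max() <= 3500.0
        assert set(s.columns) >= {"site_id", "lon", "lat", "map_mm", "protected", "noise"}

    def test_deterministic(self):
        a = simulate_sites(25, (300.0, 3500.0), 150.0, seed=9)
        b = simulate_sites(25, (300.0, 3500.0), 150.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_range(self):
        with pytest.raises(ValueError):
            simulate_sites(10, (500.0, 500.0), 100.0, seed=0)

    def test_iid_noise_when_range_zero(self):
        """Moran's I of the noise field sits in the permutation null band."""
        s = simulate_sites(80, (300.0, 3500.0), 0.0, seed=5)
        z = s["noise"].to_numpy()
        d = distance_matrix_km(s["lon"].to_numpy(), s["lat"].to_numpy())
        w = 1.0 / np.maximum(d, 1.0)
        np.fill_diagonal(w, 0.0)

        def moran(v):
            v = v - v.mean()
            return len(v) / w.sum() * (v @ w @ v) / (v @ v)

        obs = moran(z)
        rng = np.random.default_rng(0)
        null = np.array([moran(rng.permutation(z)) for _ in range(499)])
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= obs <= hi

    def test_spatial_noise_is_autocorrelated(self):
        s = simulate_sites(80, (300.0, 3500.0), 800.0, seed=5)
        z = s["noise"].to_numpy()
        d = distance_matrix_km(s["lon"].to_numpy(), s["lat"].to_numpy())
        w = 1.0 / np.maximum(d, 1.0)
        np.fill_diagonal(w, 0.0)
        v = z - z.mean()
        obs = len(v) / w.sum() * (v @ w @ v) / (v @ v)
        assert obs > 0.005  # positive spatial association


class TestAssembleCommunities:
    def test_wide_breadth_limit(self, bd_tree):
        niche = simulate_niche(bd_tree, 0.5, 8000.0, 1800.0, seed=2)
        sites = simulate_sites(5, (300.0, 3500.0), 100.0, seed=2)
        niche_vec = np.array([niche[g] for g in sorted(niche)])
        map_vec = sites["map_mm"].to_numpy()
        kern = np.exp(-((map_vec[:, None] - niche_vec[None, :]) ** 2) / (2 * 1e8 ** 2))
        prob = 10 * kern / kern.sum(axis=1, keepdims=True)
        assert prob.max() - prob.min() < 1e-6

    def test_occupancy_tracks_niche_distance(self):
        """A dry genus occupies dry sites more often, per the Gaussian kernel."""
        t = L.simulate_tree(30, 1.0, 0.0, seed=4)
        niches = {g: 2000.0 for g in t.tip_labels}
        dry_g = t.tip_labels[0]
        niches[dry_g] = 500.0
        sites = pd.DataFrame({"site_id": ["dry", "wet"], "lon": [0.0, 1.0],
                              "lat": [0.0, 1.0], "map_mm": [600.0, 3000.0],
                              "protected": [0, 0], "noise": [0.0, 0.0]})
        hits = np.zeros(2)
        for s in range(400):
            m = L.assemble_communities(t, niches, sites, 450.0, 10, seed=s)
            hits += m[dry_g].to_numpy()
        assert hits[0] > hits[1]

    def test_equal_map_equal_richness(self, bd_tree):
        niche = simulate_niche(bd_tree, 0.5, 8000.0, 1800.0, seed=3)
        sites = pd.DataFrame({"site_id": [f"S{i}" for i in range(6)],
                              "lon": np.zeros(6), "lat": np.zeros(6),
                              "map_mm": np.full(6, 1500.0),
                              "protected": np.zeros(6, int), "noise": np.zeros(6)})
        rich = np.zeros(6)
        for s in range(200):
            m = L.assemble_communities(bd_tree, niche, sites, 450.0, 12, seed=s)
            rich += m.sum(axis=1).to_numpy()
        rich /= 200
        assert rich.std() < 0.05 * rich.mean() + 1.0

    def test_base_richness_bound(self, bd_tree):
        niche = simulate_niche(bd_tree, 0.5, 8000.0, 1800.0, seed=3)
        sites = simulate_sites(4, (300.0, 3500.0), 100.0, seed=3)
        with pytest.raises(ValueError):
            L.assemble_communities(bd_tree, niche, sites, 450.0, 100, seed=0)


class TestMaskGenera:
    def test_study_proportions(self):
        tree = L.simulate_tree(920, 1.0, 0.2, seed=2)
        mat = pd.DataFrame(np.ones((2, 920), dtype=int), index=["a", "b"],
                           columns=tree.tip_labels)
        pruned, cmap = L.mask_genera(mat, tree, 68 / 920, seed=2)
        assert len(cmap) == 68 and pruned.n_tips == 852

    def test_mdcc_is_ancestral(self, bd_tree):
        mat = pd.DataFrame(np.ones((2, 40), dtype=int), index=["a", "b"],
                           columns=bd_tree.tip_labels)
        pruned, cmap = L.mask_genera(mat, bd_tree, 0.2, seed=8)
        for genus, clade in cmap.items():
            anc = bd_tree.mrca(set(clade) | {genus})
            under = {lf.taxon.label for lf in anc.leaf_iter()}
            assert set(clade) <= under and genus in under

    def test_deterministic(self, bd_tree):
        mat = pd.DataFrame(np.ones((2, 40), dtype=int), index=["a", "b"],
                           columns=bd_tree.tip_labels)
        _, c1 = L.mask_genera(mat, bd_tree, 0.2, seed=5)
        _, c2 = L.mask_genera(mat, bd_tree, 0.2, seed=5)
        assert c1 == c2

    def test_leaves_at_least_three(self, toy_tree):
        mat = pd.DataFrame(np.ones((2, 3), dtype=int), index=["a", "b"],
                           columns=["A", "B", "C"])
        with pytest.raises(ValueError):
            L.mask_genera(mat, toy_tree, 0.9, seed=0)


class TestDataset:
    def test_round_trip(self, tmp_path, small_dataset):
        small_dataset.write(tmp_path)
        back = L.SyntheticDataset.read(tmp_path)
        assert back.truth == small_dataset.truth
        pd.testing.assert_frame_equal(back.matrix, small_dataset.matrix)
        pd.testing.assert_frame_equal(back.sites, small_dataset.sites)
        assert back.niches == pytest.approx(small_dataset.niches)
        assert L.write_newick(back.tree) == L.write_newick(small_dataset.tree)

    def test_truth_records_config(self, small_dataset):
        cfg = SimulationConfig(n_tips=80, n_sites=40, seed=1, preset="ech")
        for k in ("n_tips", "n_sites", "seed", "lambda_true", "sigma2", "niche_breadth"):
            assert small_dataset.truth[k] == getattr(cfg, k)

    def test_matrix_consistent_with_tree_and_sites(self, small_dataset):
        assert set(small_dataset.matrix.columns) <= set(small_dataset.tree.tip_labels)
        assert list(small_dataset.matrix.index) == list(small_dataset.sites["site_id"])


class TestEchPreset:
    def test_pools_are_disjoint_clades(self, small_dataset):
        dry = set(small_dataset.truth["dry_clade_tips"])
        wet = set(small_dataset.truth["wet_clade_tips"])
        assert dry and wet and not (dry & wet)

    def test_interior_ld_peak(self):
        """Max LD falls strictly between the dry and wet pool means, and the
        MAP-decile LD profile peaks in an interior decile, in >= 18/20 seeds."""
        peak_ok = 0
        max_ok = 0
        n_seeds = 20
        for s in range(n_seeds):
            ds = L.make_dataset(SimulationConfig(n_tips=200, n_sites=200, seed=s,
                                                 preset="ech"))
            tab = L.ses_pd(ds.matrix, ds.tree, n_null=99, seed=s)
            m = tab.join(ds.sites.set_index("site_id"))
            ok = m[m["flag"] == "ok"]
            dec = pd.qcut(ok["map_mm"], 10, labels=False)
            if 0 < ok.groupby(dec)["ld"].mean().idxmax() < 9:
                peak_ok += 1
            mm = ok.loc[ok["ld"].idxmax(), "map_mm"]
            if ds.truth["dry_mean"] < mm < ds.truth["wet_mean"]:
                max_ok += 1
        assert peak_ok >= 18
        assert max_ok >= 18
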