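"""Generator contracts: tree process, random fields, niches, traits,
missingness, mortality, and bitwise reproducibility."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hydrisk.grids import cell_rowcol
from hydrisk.impute import compute_hsm
from hydrisk.synthetic import (
    SyntheticWorldConfig,
    apply_missingness,
    brownian_tips,
    simulate_environment,
    simulate_mortality,
    simulate_niches_and_ranges,
    simulate_phylogeny,
    simulate_traits,
    simulate_world,
    tree_depth_of,
    yule_forward_leaf_count,
)


class TestPhylogeny:
    def test_single_genus_single_species_is_one_leaf_at_full_depth(self):
        p = simulate_phylogeny(1, [1], tree_depth=50.0, seed=3)
        leaves = list(p.tree.leaf_node_iter())
        assert len(leaves) == 1
        assert leaves[0].distance_from_root() == pytest.approx(50.0)

    def test_backbone_is_binary_with_n_minus_one_internal_nodes(self):
        p = simulate_phylogeny(17, (4, 2), tree_depth=80.0, seed=1)
        internal = [
            n for n in p.genus_tree.preorder_node_iter() if not n.is_leaf()
        ]
        assert len(internal) == 16
        assert all(len(n.child_nodes()) == 2 for n in internal)

    def test_species_leaves_are_ultrametric_at_tree_depth(self):
        p = simulate_phylogeny(8, (5, 2), tree_depth=100.0, seed=2)
        depths = [lf.distance_from_root() for lf in p.tree.leaf_node_iter()]
        assert np.allclose(depths, 100.0)
        assert set(p.species_to_genus.values()) <= set(p.genera)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            simulate_phylogeny(0, 3, 10.0)
        with pytest.raises(ValueError):
            simulate_phylogeny(5, 3, -1.0)

    def test_yule_mean_leaf_count_matches_analytic_growth(self):
        # E[N(t)] = e^{lambda t} for a pure-birth process started from one
        # lineage; Monte-Carlo mean compared at 4 standard errors.
        rng = np.random.default_rng(99)
        t, lam, n = 1.5, 1.0, 1500
        counts = np.array([yule_forward_leaf_count(t, lam, rng) for _ in range(n)])
        expected = np.exp(lam * t)
        se = counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - expected) < 4 * se

    def test_brownian_tip_variance_and_covariance_match_tree(self):
        # Var(tip) = rate * depth(tip); Cov(tip_i, tip_j) = rate * depth(MRCA).
        p = simulate_phylogeny(6, (2, 2), tree_depth=50.0, seed=5)
        rate = 0.04
        sims = np.stack(
            [
                brownian_tips(p.tree, rate, np.random.default_rng(s)).to_numpy()
                for s in range(600)
            ]
        )
        labels = sorted(p.species_to_genus)
        depths = {
            lf.taxon.label: lf.distance_from_root() for lf in p.tree.leaf_node_iter()
        }
        var = sims.var(axis=0, ddof=1)
        for i, lab in enumerate(labels):
            expected = rate * depths[lab]
            assert var[i] == pytest.approx(expected, rel=0.25)
        # congeneric pair shares all but the shallow species edges
        genus = p.species_to_genus[labels[0]]
        sibs = [i for i, lab in enumerate(labels) if p.species_to_genus[lab] == genus]
        if len(sibs) >= 2:
            cov = np.cov(sims[:, sibs[0]], sims[:, sibs[1]])[0, 1]
            shared = rate * (depths[labels[sibs[0]]] - 5.0)  # species edges are 10% of 50
            assert cov == pytest.approx(shared, rel=0.3)


class TestEnvironment:
    def test_zero_sd_gives_constant_zero_layers(self):
        env = simulate_environment((10, 10), 3, corr_length=2.0, sd=0.0, seed=0)
        assert np.all(env.layers == 0.0)

    def test_zero_corr_length_is_iid(self):
        env = simulate_environment((60, 60), 1, corr_length=0.0, sd=1.0, seed=1)
        lay = env.layers[0]
        r = np.corrcoef(lay[:, :-1].ravel(), lay[:, 1:].ravel())[0, 1]
        assert abs(r) < 3 / np.sqrt(lay.size)

    def test_correlogram_matches_gaussian_kernel_autocorrelation(self):
        # smoothing white noise with a Gaussian kernel of scale s gives
        # lag-h autocorrelation exp(-h^2 / (4 s^2))
        s = 5.0
        env = simulate_environment((120, 120), 1, corr_length=s, sd=1.0, seed=2)
        lay = env.layers[0]
        for h in (1, 3, 5, 8):
            emp = np.corrcoef(lay[:, :-h].ravel(), lay[:, h:].ravel())[0, 1]
            assert emp == pytest.approx(np.exp(-(h**2) / (4 * s**2)), abs=0.1)

    def test_mean_and_sd_standardized(self):
        env = simulate_environment((30, 30), 2, 3.0, sd=2.5, seed=3)
        for lay in env.layers:
            assert lay.mean() == pytest.approx(0.0, abs=1e-12)
            assert lay.std() == pytest.approx(2.5, abs=1e-10)

    def test_zero_sized_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_environment((0, 5), 1, 1.0)


class TestNichesAndRanges:
    @pytest.fixture(scope="class")
    def setup(self):
        p = simulate_phylogeny(10, (3, 2), 100.0, seed=4)
        env = simulate_environment((15, 15), 2, 3.0, 1.0, seed=4)
        return p, env

    def test_infinite_breadth_occupies_all_cells(self, setup):
        p, env = setup
        rs = simulate_niches_and_ranges(p, env, 0.5, np.inf, seed=0)
        assert all(len(c) == env.n_cells for c in rs.cells.values())

    def test_occupancy_equals_per_cell_threshold_oracle(self, setup):
        p, env = setup
        breadth = 0.8
        rs = simulate_niches_and_ranges(p, env, 0.5, breadth, seed=1)
        axis = env.layers[0].ravel()
        for sp in rs.species:
            if sp in rs.widened:
                continue
            oracle = {
                c for c in range(env.n_cells)
                if abs(axis[c] - rs.optima[sp]) <= breadth
            }
            assert set(rs.cells[sp]) == oracle

    def test_every_species_occupies_at_least_one_cell(self, setup):
        p, env = setup
        rs = simulate_niches_and_ranges(p, env, 0.5, 1e-6, seed=2)
        assert all(len(c) >= 1 for c in rs.cells.values())
        assert len(rs.widened) > 0  # tiny breadth forces widening


class TestTraits:
    def test_degenerate_parameters_reproduce_root_states(self):
        p = simulate_phylogeny(5, (2, 1), 50.0, seed=6)
        env = pd.DataFrame(
            0.0, index=sorted(p.species_to_genus), columns=["env1", "env2"]
        )
        cfg = SyntheticWorldConfig(
            bm_rate_pmin=0.0, bm_rate_p50=0.0,
            env_effect=(0.0, 0.0), noise_sd=0.0,
        )
        tab, truth = simulate_traits(p, env, cfg, seed=0)
        assert np.allclose(tab["p_min"], cfg.pmin_root)
        assert np.allclose(tab["p50"], cfg.p50_root)
        assert (tab["p88"] < tab["p50"]).all()

    def test_all_p50_negative_and_truth_recorded(self, world):
        tab = world.traits_truth
        assert (tab["p50"] < 0).all()
        assert (tab["p88"] < tab["p50"]).all()
        assert "env_effect" in world.truth and "shift_p50" in world.truth

    def test_trait_correlation_near_target_for_pure_bm(self):
        # with env and noise off, corr(P_min, P50) across tips estimates the
        # shared-component weight; averaged over seeds
        target = 0.7
        cors = []
        for s in range(8):
            p = simulate_phylogeny(40, (4, 2), 100.0, seed=100 + s)
            env = pd.DataFrame(
                0.0, index=sorted(p.species_to_genus), columns=["env1"]
            )
            cfg = SyntheticWorldConfig(
                trait_corr=target, env_effect=(0.0,), noise_sd=0.0,
                bm_rate_pmin=0.02, bm_rate_p50=0.02,
            )
            tab, _ = simulate_traits(p, env, cfg, seed=200 + s)
            cors.append(np.corrcoef(tab["p_min"], tab["p50"])[0, 1])
        assert np.mean(cors) == pytest.approx(target, abs=0.12)

    def test_inconsistent_species_sets_rejected(self):
        p = simulate_phylogeny(3, (2, 1), 10.0, seed=0)
        env = pd.DataFrame(0.0, index=["nobody"], columns=["env1"])
        with pytest.raises(ValueError):
            simulate_traits(p, env, SyntheticWorldConfig(), seed=0)


class TestMissingness:
    def test_fraction_one_keeps_table_unchanged(self, world):
        out = apply_missingness(world.traits_truth, 1.0, seed=0)
        for c in ("p_min", "p50", "p88"):
            assert out[c].equals(world.traits_truth[c])

    def test_observed_count_in_binomial_interval(self, world):
        frac = 0.3
        out = apply_missingness(world.traits_truth, frac, seed=1)
        n = len(out)
        k = out["p_min"].notna().sum()
        sd = np.sqrt(n * frac * (1 - frac))
        assert abs(k - n * frac) < 2.6 * sd

    def test_clade_and_genus_never_masked(self, world):
        out = apply_missingness(world.traits_truth, 0.05, seed=2)
        assert out["clade"].notna().all()
        assert out["genus"].notna().all()

    def test_invalid_fraction_rejected(self, world):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                apply_missingness(world.traits_truth, bad)


class TestMortality:
    def test_huge_negative_intercept_gives_zero_events(self, world):
        out = simulate_mortality(world.assemblage, {"intercept": -50.0}, seed=0)
        assert len(out) == 0

    def test_null_coefficients_give_half_event_rate(self, world):
        out = simulate_mortality(world.assemblage, {"intercept": 0.0}, seed=1)
        rate = out.attrs["event_rate_woody"]
        n_woody = (world.assemblage["richness"].ravel() >= 1).sum()
        assert abs(rate - 0.5) < 2.6 * np.sqrt(0.25 / n_woody)

    def test_event_rate_tracks_logistic_curve_in_eta_bins(self, world):
        coefs = world.config.mortality_coefs
        grid = world.assemblage
        eta = np.full(grid["richness"].size, coefs["intercept"])
        for name, c in coefs.items():
            if name != "intercept":
                eta += c * np.nan_to_num(grid[name].ravel())
        prob = 1 / (1 + np.exp(-eta))
        rng = np.random.default_rng(0)
        events = np.zeros_like(prob)
        reps = 40
        for s in range(reps):
            out = simulate_mortality(grid, coefs, seed=1000 + s)
            hit = np.zeros_like(prob)
            hit[np.unique(out["cell"])] = 1
            events += hit
        emp = events / reps
        for lo, hi in [(0.0, 0.1), (0.1, 0.3), (0.3, 0.7)]:
            sel = (prob >= lo) & (prob < hi)
            if sel.sum() < 30:
                continue
            n_eff = sel.sum() * reps
            pbar = prob[sel].mean()
            assert abs(emp[sel].mean() - pbar) < 4 * np.sqrt(pbar * (1 - pbar) / n_eff)

    def test_unknown_metric_rejected(self, world):
        with pytest.raises(KeyError):
            simulate_mortality(world.assemblage, {"intercept": 0.0, "nope": 1.0})

    def test_events_lie_on_grid_and_carry_occupying_species(self, world):
        nrows, ncols = world.config.grid_shape
        m = world.mortality
        assert ((m["x"] > 0) & (m["x"] < ncols)).all()
        assert ((m["y"] > 0) & (m["y"] < nrows)).all()
        occ = world.occupancy.tocsc()
        species = world.ranges.species
        for _, row in m.head(20).iterrows():
            cell = int(row["cell"])
            occupants = {
                species[i]
                for i in occ.indices[occ.indptr[cell]: occ.indptr[cell + 1]]
            }
            assert len(occupants) >= 1
            if row["species"] is not None:
                assert row["species"] in occupants


class TestReproducibility:
    def test_identical_config_and_seed_is_bit_identical(self):
        cfg = SyntheticWorldConfig(seed=11, n_genera=20, grid_shape=(12, 12))
        w1, w2 = simulate_world(cfg), simulate_world(cfg)
        assert np.array_equal(w1.env.layers, w2.env.layers)
        assert w1.traits_truth.equals(w2.traits_truth)
        assert w1.traits_observed.equals(w2.traits_observed)
        assert w1.mortality.equals(w2.mortality)
        assert (w1.occupancy != w2.occupancy).nnz == 0

    def test_truth_record_recomputes_event_probabilities(self, world):
        coefs = world.truth["mortality_coefs"]
        eta = np.full(world.assemblage["richness"].size, coefs["intercept"])
        for name, c in coefs.items():
            if name != "intercept":
                eta += c * np.nan_to_num(world.assemblage[name].ravel())
        assert np.isfinite(eta).all()
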