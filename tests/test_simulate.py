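"""Synthetic-data generator: determinism, planted structure, round-trips."""

import numpy as np
import pandas as pd
import pytest

from snakedent import (
    SUBJUGATION_MODES,
    SimConfig,
    lambda_transform,
    node_ids,
    pic,
    read_ecology_table,
    read_newick,
    read_tooth_table,
    relative_posterior_tooth_length,
    sim_bm_trait,
    sim_bundle,
    sim_ecology,
    sim_er_discrete,
    sim_threshold_trait,
    sim_tooth_table,
    sim_yule_tree,
    vcv_matrix,
)


class TestYule:
    def test_two_tip_cherry(self):
        t = sim_yule_tree(2, seed=0)
        assert t.n_tips == 2
        assert len(t.root.children) == 2

    def test_determinism(self):
        a = sim_yule_tree(25, seed=42).write_newick()
        b = sim_yule_tree(25, seed=42).write_newick()
        assert a == b
        assert sim_yule_tree(25, seed=43).write_newick() != a

    def test_ultrametric(self):
        t = sim_yule_tree(30, seed=1)
        depths = np.array(list(t.depths().values()))
        np.testing.assert_allclose(depths, depths[0], rtol=1e-10)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            sim_yule_tree(1)

    def test_lineage_growth_rate(self):
        """Expected lineage count grows ~exp(birth_rate * t) in a pure-birth
        process: tree height should be ~log(n)/birth_rate on average."""
        rate = 2.0
        heights = [sim_yule_tree(64, rate, seed=i).height for i in range(120)]
        expected = np.log(64) / rate
        assert np.mean(heights) == pytest.approx(expected, rel=0.2)


class TestBMTrait:
    def test_lambda_zero_gives_uncorrelated_tips(self):
        tree = sim_yule_tree(8, seed=2)
        draws = np.stack(
            [sim_bm_trait(tree, lam=0.0, seed=i).to_numpy() for i in range(800)]
        )
        cov = np.cov(draws.T)
        off = cov[~np.eye(8, dtype=bool)]
        diag = np.diag(cov)
        target = np.diag(vcv_matrix(tree).matrix)
        np.testing.assert_allclose(diag, target, rtol=0.25)
        assert np.abs(off).max() < 0.35 * diag.max()

    def test_contrast_variance_matches_rate(self):
        tree = sim_yule_tree(40, seed=3)
        sigma2 = 1.7
        cs = np.concatenate(
            [pic(tree, sim_bm_trait(tree, sigma2=sigma2, seed=i)) for i in range(150)]
        )
        assert cs.var() == pytest.approx(sigma2, rel=0.06)

    def test_zero_rate_gives_constant(self):
        tree = sim_yule_tree(10, seed=4)
        assert sim_bm_trait(tree, sigma2=0.0, seed=5).nunique() == 1


class TestERDiscrete:
    def test_q_zero_shares_root_state(self):
        tree = sim_yule_tree(20, seed=6)
        tips, nodes = sim_er_discrete(tree, 0.0, k=3, seed=7)
        assert len(set(tips.values())) == 1

    def test_large_q_approaches_uniform(self):
        tree = sim_yule_tree(40, seed=8).scale_to_height(50.0)
        freqs = []
        for i in range(60):
            tips, _ = sim_er_discrete(tree, 5.0, k=2, seed=i)
            freqs.append(np.mean([s == "state0" for s in tips.values()]))
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.05)

    def test_truth_consistent_with_tips(self):
        tree = sim_yule_tree(15, seed=9)
        tips, nodes = sim_er_discrete(tree, 0.4, k=3, seed=10)
        ids = node_ids(tree)
        for t in tree.tips():
            assert nodes[ids[t]] == tips[t.label]


class TestThresholdSim:
    def test_states_match_liability_intervals(self):
        tree = sim_yule_tree(25, seed=11)
        thr = (0.0, 1.2)
        tips, liab, states = sim_threshold_trait(tree, thr, seed=12)
        for nid in liab.index:
            x = liab[nid]
            expected = "state0" if x < 0 else ("state1" if x < 1.2 else "state2")
            assert states[nid] == expected

    def test_root_threshold_balance(self):
        """With a single threshold at the root value, tip states are ~50/50."""
        fractions = []
        for i in range(60):
            tree = sim_yule_tree(30, seed=500 + i)
            tips, _, _ = sim_threshold_trait(tree, (0.0,), seed=i)
            fractions.append(np.mean([s == "state0" for s in tips.values()]))
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.07)

    def test_decreasing_thresholds_rejected(self):
        tree = sim_yule_tree(5, seed=13)
        with pytest.raises(ValueError):
            sim_threshold_trait(tree, (1.0, 0.5))


class TestToothTable:
    @staticmethod
    def traits_frame(n, c):
        return pd.DataFrame(
            {
                "cranium_length_mm": 30.0,
                "maxilla_length_mm": 10.0,
                "n_teeth": 15,
                "enlargement_c": c,
                "groove_p": 0.5,
            },
            index=[f"sp{i:03d}" for i in range(1, n + 1)],
        )

    def test_noise_free_rptl_recovers_c_exactly(self):
        cfg = SimConfig(measurement_noise_sd=0.0, missing_tooth_probability=0.0)
        rows = sim_tooth_table(cfg, self.traits_frame(5, 1.3), seed=0)
        for row in rows:
            assert relative_posterior_tooth_length(row) == pytest.approx(
                1.3, abs=1e-10
            )

    def test_noisy_rptl_unbiased(self):
        cfg = SimConfig(measurement_noise_sd=0.08, missing_tooth_probability=0.0)
        c = 0.9
        rows = sim_tooth_table(cfg, self.traits_frame(400, c), seed=1)
        errs = np.array(
            [relative_posterior_tooth_length(r) - c for r in rows]
        )
        se = errs.std() / np.sqrt(errs.size)
        assert abs(errs.mean()) < 2.5 * se + 1e-3

    def test_missing_posterior_tooth_still_defined(self):
        cfg = SimConfig(measurement_noise_sd=0.0, missing_tooth_probability=0.0)
        rows = sim_tooth_table(cfg, self.traits_frame(1, 2.0), seed=2)
        row = rows[0]
        row.teeth[-1].present = False
        row.teeth[-1].ankylosed = False
        row.teeth[-1].length_mm = None
        assert relative_posterior_tooth_length(row) == pytest.approx(2.0, abs=1e-10)


class TestEcologySim:
    def test_modes_cover_all_categories(self):
        tree = sim_yule_tree(150, seed=14)
        eco = sim_ecology(tree, SimConfig(n_unknown_mode=0), seed=15)
        assert set(eco["mode"]) == set(SUBJUGATION_MODES)

    def test_unknown_modes_planted(self):
        tree = sim_yule_tree(50, seed=16)
        eco = sim_ecology(tree, SimConfig(n_unknown_mode=4), seed=17)
        assert (eco["mode"] == "unknown").sum() == 4

    def test_counts_nonnegative_integers(self):
        tree = sim_yule_tree(30, seed=18)
        eco = sim_ecology(tree, SimConfig(), seed=19)
        counts = eco[eco.columns[2:]]
        assert (counts >= 0).all().all()
        assert (counts.sum(axis=1) >= 1).all()


class TestBundle:
    def test_roundtrip_through_readers(self, tmp_path):
        bundle = sim_bundle(SimConfig(seed=20, n_species=25))
        out = bundle.write(tmp_path / "b")
        tree = read_newick(out / "tree.nwk")
        assert tree.tip_labels == bundle.tree.tip_labels
        rows = read_tooth_table(out / "tooth_rows.csv")
        assert {r.species for r in rows} == set(tree.tip_labels)
        eco = read_ecology_table(out / "ecology.csv")
        assert list(eco.index) == tree.tip_labels

    def test_bundle_determinism(self, tmp_path):
        a = sim_bundle(SimConfig(seed=21, n_species=20))
        b = sim_bundle(SimConfig(seed=21, n_species=20))
        assert a.tree.write_newick() == b.tree.write_newick()
        pd.testing.assert_frame_equal(a.ecology, b.ecology)
        pd.testing.assert_frame_equal(a.species_traits, b.species_traits)

    def test_front_fanged_states_assigned(self):
        bundle = sim_bundle(SimConfig(seed=22))
        eco, taxa = bundle.ecology, bundle.taxa
        ff = taxa.index[taxa["is_front_fanged"]]
        assert len(ff) >= 3
        assert set(eco.loc[ff, "fang_state"]) <= {"hollow", "tubular"}
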