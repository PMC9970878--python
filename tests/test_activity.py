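"""Substrate binning, control draws, the activity statistic and MK tables."""

import numpy as np
import pandas as pd
import pytest

import sphinks as sp
from sphinks.io import Interactome
from .conftest import make_matrix


def toy_network(sops, tau=0.5):
    """Build an interactome from {kinase: [(site, omega)]}."""
    rows = [(k, s, w, 1.0, 1) for k, members in sops.items() for s, w in members]
    return Interactome(pd.DataFrame(rows, columns=Interactome._COLS), tau=tau)


class TestBinSubstrates:
    def test_equal_count_bins(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(50, 4)),
                        features=[f"G{i}_S1" for i in range(50)])
        bins = sp.bin_substrates(m, n_bins=25)
        counts = bins.bins.value_counts()
        assert len(counts) == 25 and (counts == 2).all()

    def test_extremes_never_share_a_bin(self):
        means = np.arange(1.0, 101.0)
        m = make_matrix(np.column_stack([means, means]),
                        features=[f"G{i}_S1" for i in range(100)])
        bins = sp.bin_substrates(m, n_bins=25)
        assert bins.bins.iloc[0] != bins.bins.iloc[99]
        assert bins.bins.iloc[0] == 1 and bins.bins.iloc[99] == 25

    def test_tied_means_split_stably(self):
        m = make_matrix(np.ones((6, 3)), features=[f"G{i}_S1" for i in range(6)])
        a = sp.bin_substrates(m, n_bins=3)
        b = sp.bin_substrates(m, n_bins=3)
        pd.testing.assert_series_equal(a.bins, b.bins)
        assert sorted(a.bins.value_counts()) == [2, 2, 2]

    def test_invalid_bins_error(self, tiny_matrix):
        with pytest.raises(ValueError):
            sp.bin_substrates(tiny_matrix, n_bins=0)


class TestDrawControls:
    def _setup(self, n_sites=60, n_controls=10):
        rng = np.random.default_rng(1)
        sites = [f"G{i}_S1" for i in range(n_sites)]
        m = make_matrix(rng.normal(size=(n_sites, 5)), features=sites)
        net = toy_network({"K1": [(sites[0], 0.9), (sites[1], 0.8), (sites[2], 0.7)]})
        bins = sp.bin_substrates(m, n_bins=5)
        return m, net, bins, n_controls

    def test_cardinality_hundredfold(self):
        m, net, bins, _ = self._setup()
        controls = sp.draw_controls(net, bins, n_controls=10, seed=0)
        total = sum(len(v) for v in controls.controls.values())
        assert total == 10 * 3  # n_controls per SOPS substrate

    def test_same_seed_identical(self):
        m, net, bins, n = self._setup()
        a = sp.draw_controls(net, bins, n_controls=n, seed=5)
        b = sp.draw_controls(net, bins, n_controls=n, seed=5)
        assert a.controls == b.controls

    def test_controls_match_substrate_bins(self):
        m, net, bins, n = self._setup()
        controls = sp.draw_controls(net, bins, n_controls=n, seed=2)
        for (kinase, substrate), ctrl in controls.controls.items():
            b = bins.bins[substrate]
            assert all(bins.bins[c] == b for c in ctrl)

    def test_controls_exclude_own_sops(self):
        m, net, bins, n = self._setup()
        controls = sp.draw_controls(net, bins, n_controls=n, seed=3)
        sops = {s for _, s in controls.controls}
        for ctrl in controls.controls.values():
            assert not (set(ctrl) & sops)

    def test_small_pool_with_replacement_flagged(self):
        sites = [f"G{i}_S1" for i in range(6)]
        m = make_matrix(np.arange(18, dtype=float).reshape(6, 3), features=sites)
        net = toy_network({"K1": [(sites[0], 0.9)]})
        bins = sp.bin_substrates(m, n_bins=2)
        controls = sp.draw_controls(net, bins, n_controls=10, seed=0)
        assert ("K1", sites[0]) in controls.with_replacement
        assert len(controls.controls[("K1", sites[0])]) == 10


class TestMkActivity:
    def _world(self, sub_abund, ctrl_abund, sub_w=(0.9, 0.6, 0.5), ctrl_w=0.5):
        """Two+ substrates and a shared control pool with fixed abundances."""
        sub_sites = [f"SUB{i}_S1" for i in range(len(sub_abund))]
        ctrl_sites = [f"CTL{i}_S1" for i in range(len(ctrl_abund))]
        vals = np.array(list(sub_abund) + list(ctrl_abund), dtype=float)[:, None]
        m = make_matrix(vals, features=sub_sites + ctrl_sites, samples=["s0"])
        net = toy_network({"K1": list(zip(sub_sites, sub_w))})
        scores = sp.ScoreMatrix(
            pd.DataFrame(ctrl_w, index=["K1"], columns=sub_sites + ctrl_sites), 1, 0)
        controls = sp.ControlAssignment(
            {("K1", s): list(ctrl_sites) for s in sub_sites}, len(ctrl_sites), 0, set())
        return m, net, scores, controls

    def test_displayed_equation_worked_example(self):
        # SOPS {omega .9 at t=2, omega .6 at t=1}, controls omega .5 at t=0:
        # Act = (0.9*2 + 0.6*1)/1.5 - 0 = 1.6
        m, net, scores, controls = self._world(
            sub_abund=[2.0, 1.0, 0.0], ctrl_abund=[0.0, 0.0],
            sub_w=(0.9, 0.6, 0.0))
        # drop the zero-weight third substrate from the network
        net = toy_network({"K1": [("SUB0_S1", 0.9), ("SUB1_S1", 0.6), ("SUB2_S1", 1e-12)]})
        act = sp.mk_activity("s0", "K1", net, m, controls, scores)
        assert act == pytest.approx(1.6, abs=1e-9)

    def test_identical_substrate_and_control_abundances_zero(self):
        m, net, scores, controls = self._world(
            sub_abund=[1.5, 1.5, 1.5], ctrl_abund=[1.5, 1.5])
        act = sp.mk_activity("s0", "K1", net, m, controls, scores)
        assert act == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self):
        m, net, scores, controls = self._world(
            sub_abund=[2.0, 1.0, 3.0], ctrl_abund=[0.5, -1.0])
        act = sp.mk_activity("s0", "K1", net, m, controls, scores)
        shifted = sp.AbundanceMatrix(m.data + 7.0, scale="log2")
        act2 = sp.mk_activity("s0", "K1", net, shifted, controls, scores)
        assert act2 == pytest.approx(act, abs=1e-9)

    def test_scaling_equivariance(self):
        m, net, scores, controls = self._world(
            sub_abund=[2.0, 1.0, 3.0], ctrl_abund=[0.5, -1.0])
        act = sp.mk_activity("s0", "K1", net, m, controls, scores)
        scaled = sp.AbundanceMatrix(m.data * 3.0, scale="log2")
        act2 = sp.mk_activity("s0", "K1", net, scaled, controls, scores)
        assert act2 == pytest.approx(3.0 * act, abs=1e-9)

    def test_min_sops_enforced(self):
        m, net, scores, controls = self._world(
            sub_abund=[2.0, 1.0, 0.0], ctrl_abund=[0.0])
        net = toy_network({"K1": [("SUB0_S1", 0.9)]})
        with pytest.raises(ValueError, match="below minimum"):
            sp.mk_activity("s0", "K1", net, m, controls, scores)


class TestActivityMatrix:
    def test_sample_permutation_equivariance(self, smoke_pipeline):
        res, truth, labels, proteome, phospho = smoke_pipeline
        perm = list(phospho.samples)[::-1]
        ph2 = sp.AbundanceMatrix(phospho.data[perm], scale="log2")
        act2 = sp.activity_matrix(res.network, ph2, res.controls, res.scores)
        pd.testing.assert_frame_equal(res.activities[perm], act2)

    def test_empty_interactome_warns_empty(self, smoke_cohort):
        _, phospho, _, _ = smoke_cohort
        empty = Interactome(pd.DataFrame(columns=Interactome._COLS), tau=0.5)
        scores = sp.ScoreMatrix(pd.DataFrame(index=[], columns=phospho.features,
                                             dtype=float), 1, 0)
        controls = sp.ControlAssignment({}, 10, 0, set())
        act = sp.activity_matrix(empty, phospho, controls, scores)
        assert act.empty


class TestSubtypeMasterKinases:
    def test_full_separation_selected_with_extreme_stats(self):
        act = pd.DataFrame(
            [[5.0, 6.0, 5.5, 0.0, -0.2, 0.1],
             [1.0, 1.1, 0.9, 1.0, 1.1, 0.9]],
            index=["KA", "KB"],
            columns=[f"s{i}" for i in range(6)])
        labels = pd.Series(["X"] * 3 + ["Y"] * 3, index=act.columns)
        table = sp.subtype_master_kinases(act, labels, effect_min=0.3, p_max=0.2)
        row = table[(table.kinase == "KA") & (table.subtype == "X")]
        assert len(row) == 1
        assert row.iloc[0].effect_size == pytest.approx(1.0)
        assert row.iloc[0]["rank"] == 1
        # identical-everywhere kinase is never selected
        assert "KB" not in set(table.kinase)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        act = pd.DataFrame(rng.normal(size=(2, 12)), index=["KA", "KB"],
                           columns=[f"s{i}" for i in range(12)])
        act.loc["KA", act.columns[:6]] += 2.0
        labels = pd.Series(["X"] * 6 + ["Y"] * 6, index=act.columns)
        table = sp.subtype_master_kinases(act, labels, effect_min=0.3, p_max=0.05)
        expected = []
        for kinase in act.index:
            for subtype in ("X", "Y"):
                ins = act.loc[kinase, labels[labels == subtype].index]
                outs = act.loc[kinase, labels[labels != subtype].index]
                r = sp.mww_test(ins.to_numpy(), outs.to_numpy())
                if r.effect_size > 0.3 and r.p_value < 0.05 and r.prob_superiority > 0.5:
                    expected.append((kinase, subtype))
        assert set(zip(table.kinase, table.subtype)) == set(expected)

    def test_unlabeled_sample_excluded(self):
        act = pd.DataFrame(np.arange(8.0).reshape(1, 8), index=["KA"],
                           columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["X"] * 4 + ["Y"] * 3, index=act.columns[:7])
        table = sp.subtype_master_kinases(act, labels, effect_min=0.0, p_max=1.0)
        assert set(table.subtype) <= {"X", "Y"}

    def test_single_subtype_errors(self):
        act = pd.DataFrame(np.ones((1, 4)), index=["KA"],
                           columns=[f"s{i}" for i in range(4)])
        labels = pd.Series(["X"] * 4, index=act.columns)
        with pytest.raises(ValueError, match="2 subtypes"):
            sp.subtype_master_kinases(act, labels)
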