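"""Tree-emission HMM: emissions, EM, model selection, cluster metrics."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import popglass as pg
from popglass import maxent, treehmm
from popglass.experiments import aligned_accuracy
from popglass.treehmm import TreeHMM, TreeMode


@pytest.fixture(scope="module")
def fitted3(mode_raster):
    raster, _ = mode_raster
    return treehmm.fit(raster, 3, dict(n_restarts=2, max_iters=40), seed=9)


class TestEmissions:
    def test_edgeless_tree_is_independent_product(self):
        mode = TreeMode.independent([0.2, 0.2])
        q = np.exp(mode.log_prob(np.array([1, 0])))
        assert q == pytest.approx(0.2 * 0.8)

    def test_emission_normalizes_over_all_patterns(self):
        rng = np.random.default_rng(1)
        x = (rng.random((500, 10)) < 0.3).astype(np.uint8)
        mode = treehmm.chow_liu(x, rng.random(500))
        pats = maxent.enumerate_patterns(10).astype(np.uint8)
        assert np.exp(mode.log_prob(pats)).sum() == pytest.approx(1.0,
                                                                  abs=1e-10)

    def test_three_neuron_chain_matches_hand_computation(self):
        # chain 0 -> 1 -> 2 with hand-set tables
        parent = np.array([-1, 0, 1])
        tab = np.zeros((3, 2, 2))
        tab[0, :, 1] = np.log(0.3)
        tab[0, :, 0] = np.log(0.7)
        tab[1, 0] = np.log([0.9, 0.1])   # P(r1 | r0=0)
        tab[1, 1] = np.log([0.4, 0.6])   # P(r1 | r0=1)
        tab[2, 0] = np.log([0.8, 0.2])
        tab[2, 1] = np.log([0.5, 0.5])
        mode = TreeMode(parent, tab)
        # pattern (1, 0, 1): P = .3 * P(r1=0|1)=.4 * P(r2=1|0)=.2
        assert np.exp(mode.log_prob(np.array([1, 0, 1]))) == \
            pytest.approx(0.3 * 0.4 * 0.2)

    def test_cyclic_parent_graph_rejected(self):
        with pytest.raises(ValueError, match="forest|cycle"):
            TreeMode(np.array([1, 0]), np.zeros((2, 2, 2)))


class TestFit:
    def test_single_mode_reduces_to_chow_liu(self, mode_raster):
        raster, _ = mode_raster
        m1 = treehmm.fit(raster, 1, dict(n_restarts=1, max_iters=5), seed=2)
        direct = treehmm.chow_liu(raster.values.T, np.ones(raster.n_bins))
        assert m1.modes[0].log_prob(raster.values.T).sum() == pytest.approx(
            direct.log_prob(raster.values.T).sum())

    def test_recovers_planted_modes(self, mode_raster, fitted3):
        raster, labels = mode_raster
        pred = treehmm.assign(fitted3, raster).labels
        assert aligned_accuracy(labels, pred, 3) >= 0.95

    def test_em_loglik_nondecreasing(self, fitted3):
        hist = np.array(fitted3.diagnostics["ll_history"])
        slack = 1e-6 * np.abs(hist).max()
        assert np.all(np.diff(hist) >= -slack)

    def test_determinism(self, mode_raster):
        raster, _ = mode_raster
        cfg = dict(n_restarts=2, max_iters=15)
        m1 = treehmm.fit(raster, 3, cfg, seed=4)
        m2 = treehmm.fit(raster, 3, cfg, seed=4)
        np.testing.assert_array_equal(m1.w, m2.w)
        np.testing.assert_array_equal(m1.transitions, m2.transitions)
        for a, b in zip(m1.modes, m2.modes):
            np.testing.assert_array_equal(a.parent, b.parent)
            np.testing.assert_array_equal(a.log_table, b.log_table)

    def test_mixture_marginal_normalizes(self):
        truth = pg.make_planted_modes(10, 2, 4, 0.5, 0.05, 0.8, seed=5)
        raster, _ = pg.sample_mode_raster(truth, 1500, seed=6)
        model = treehmm.fit(raster, 2, dict(n_restarts=1, max_iters=20),
                            seed=7)
        pats = maxent.enumerate_patterns(10).astype(np.uint8)
        total = np.exp(model.marginal_log_prob(pats)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_recovery_degrades_with_mode_overlap(self):
        """More shared active neurons between modes -> worse recovery."""
        accs = []
        for overlap in (0, 2, 4):
            probs = np.full((2, 12), 0.02)
            probs[0, 0:6] = 0.5
            probs[1, 6 - overlap:12 - overlap] = 0.5
            truth = pg.synth.ModeGroundTruth(probs, np.array([[0.8, 0.2],
                                                              [0.2, 0.8]]))
            raster, labels = pg.sample_mode_raster(truth, 2500, seed=8)
            model = treehmm.fit(raster, 2, dict(n_restarts=2, max_iters=30),
                                seed=9)
            pred = treehmm.assign(model, raster).labels
            accs.append(aligned_accuracy(labels, pred, 2))
        assert accs[0] >= accs[1] >= accs[2] - 0.02
        assert accs[0] > accs[2]

    def test_more_modes_than_patterns_rejected(self):
        raster = pg.BinaryRaster(np.tile([[1], [0]], (1, 50)))
        with pytest.raises(ValueError, match="distinct patterns"):
            treehmm.fit(raster, 3)


class TestSelectNumModes:
    def test_singleton_grid(self, mode_raster):
        raster, _ = mode_raster
        M, table = treehmm.select_num_modes(
            raster, [2], dict(em_config=dict(n_restarts=1, max_iters=15)),
            seed=10)
        assert M == 2
        assert len(table) == 1

    def test_recovers_planted_mode_count(self, mode_raster):
        raster, _ = mode_raster
        M, _ = treehmm.select_num_modes(
            raster, range(1, 6),
            dict(em_config=dict(n_restarts=2, max_iters=40)), seed=6)
        assert M == 3

    def test_structureless_raster_selects_one_mode(self, mode_raster):
        raster, _ = mode_raster
        null = pg.rate_matched_shuffle(raster, seed=7)
        M, _ = treehmm.select_num_modes(
            null, range(1, 5),
            dict(em_config=dict(n_restarts=2, max_iters=30)), seed=8)
        assert M == 1


class TestAssign:
    def test_weighted_probability_arithmetic(self):
        # w=(0.9, 0.1), Q=(0.01, 0.02): weighted (0.009, 0.002) -> mode 0
        modes = [TreeMode.independent([0.1]), TreeMode.independent([0.9])]
        q0 = float(np.exp(modes[0].log_prob(np.array([1]))))
        q1 = float(np.exp(modes[1].log_prob(np.array([1]))))
        model = TreeHMM(modes, [0.95, 0.05], np.full((2, 2), 0.5))
        lab = treehmm.assign(model, pg.BinaryRaster(np.array([[1]] )))
        assert 0.95 * q0 > 0.05 * q1
        assert lab.labels[0] == 0

    def test_noiseless_emissions_recover_exactly(self):
        probs = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        truth = pg.synth.ModeGroundTruth(probs, np.full((2, 2), 0.5))
        raster, labels = pg.sample_mode_raster(truth, 300, seed=11)
        modes = [TreeMode.independent(p) for p in probs]
        model = TreeHMM(modes, truth.weights, truth.transitions)
        pred = treehmm.assign(model, raster).labels
        assert aligned_accuracy(labels, pred, 2) == 1.0

    def test_posterior_rows_normalized_and_map_consistent(self, mode_raster,
                                                          fitted3):
        raster, _ = mode_raster
        lab = treehmm.assign(fitted3, raster)
        np.testing.assert_allclose(lab.posterior.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(lab.labels,
                                      lab.posterior.argmax(axis=1))

    def test_static_equals_dynamic_for_memoryless_chain(self, mode_raster,
                                                        fitted3):
        raster, _ = mode_raster
        memoryless = TreeHMM(fitted3.modes, fitted3.w,
                             np.tile(fitted3.w, (3, 1)), fitted3.w)
        s = treehmm.assign(memoryless, raster, use_dynamics=False).labels
        d = treehmm.assign(memoryless, raster, use_dynamics=True).labels
        np.testing.assert_array_equal(s, d)


class TestReliability:
    def test_identical_sequences_fully_reliable(self):
        labs = [np.array([0, 1, 2, 1])] * 5
        per_bin, mean = treehmm.reliability_across_repeats(labs)
        np.testing.assert_allclose(per_bin, 1.0)
        assert mean == 1.0

    def test_uniform_labels_match_multinomial_modal_fraction(self):
        rng = np.random.default_rng(12)
        M, R, B = 4, 12, 2000
        labs = [rng.integers(0, M, B) for _ in range(R)]
        _, mean = treehmm.reliability_across_repeats(labs)
        # modal fraction of a uniform multinomial, by direct simulation
        sim = np.random.default_rng(13).multinomial(
            R, np.full(M, 1 / M), size=20000).max(axis=1).mean() / R
        assert mean == pytest.approx(sim, abs=0.01)

    def test_single_repeat_degenerate(self, caplog):
        per_bin, mean = treehmm.reliability_across_repeats(
            [np.array([0, 1, 0])])
        assert mean == 1.0

    def test_planted_repeats_are_reliable(self, mode_truth):
        rasters, labels = pg.make_repeat_ensemble(mode_truth, 8, 400, seed=14)
        model = treehmm.fit(rasters[0], 3, dict(n_restarts=2, max_iters=30),
                            seed=15)
        labs = [treehmm.assign(model, r).labels for r in rasters]
        _, mean = treehmm.reliability_across_repeats(labs)
        assert mean > 0.9


class TestSeparation:
    def test_dprime_formula_on_projections(self):
        # 1-D members: means 0 and 3, sds 1 and 0.5 -> d' = 2
        rng = np.random.default_rng(16)
        a = rng.normal(0, 1, (4000, 1))
        b = rng.normal(3, 0.5, (4000, 1))
        d, _, _ = treehmm._pair_dprime(a, b)
        assert d == pytest.approx(2.0, rel=0.05)

    def test_identical_member_sets_give_zero(self):
        x = np.array([[1, 0], [0, 1], [1, 1], [1, 0], [0, 1], [1, 1]],
                     dtype=np.uint8)
        labels = np.array([0, 0, 0, 1, 1, 1])
        rep = treehmm.separation(pg.BinaryRaster(x.T), labels)
        assert rep.min_dprime == pytest.approx(0.0, abs=0.3)

    def test_planted_modes_well_separated(self, mode_raster, fitted3):
        raster, _ = mode_raster
        labels = treehmm.assign(fitted3, raster).labels
        rep = treehmm.separation(raster, labels)
        assert rep.min_dprime > 1.0
        assert set(rep.table.columns) >= {"cluster_a", "cluster_b", "dprime"}


class TestShuffleControl:
    def test_symmetric_emissions_are_noop(self):
        # neuron-symmetric modes: permuting neuron identities leaves the
        # model invariant, so the control must reproduce the real d' exactly
        rng = np.random.default_rng(17)
        values = (rng.random((6, 600)) < 0.35).astype(np.uint8)
        raster = pg.BinaryRaster(values)
        modes = [TreeMode.independent(np.full(6, 0.2)),
                 TreeMode.independent(np.full(6, 0.6))]
        model = TreeHMM(modes, [0.5, 0.5], np.full((2, 2), 0.5))
        labels = treehmm.assign(model, raster).labels
        ref = treehmm.separation(raster, labels).table["dprime"].to_numpy()
        null = treehmm.shuffle_control(model, raster, labels, seed=18,
                                       n_shuffles=3)
        for s in range(3):
            got = null[null["shuffle"] == s]["dprime"].to_numpy()
            np.testing.assert_allclose(got, ref)

    def test_structured_modes_lose_separation(self, mode_raster, fitted3):
        raster, _ = mode_raster
        labels = treehmm.assign(fitted3, raster).labels
        real = treehmm.separation(raster, labels).table["dprime"].to_numpy()
        null = treehmm.shuffle_control(fitted3, raster, labels, seed=19,
                                       n_shuffles=5)["dprime"].to_numpy()
        assert mannwhitneyu(null, real, alternative="less").pvalue < 0.01

    def test_same_seed_identical(self, mode_raster, fitted3):
        raster, _ = mode_raster
        labels = treehmm.assign(fitted3, raster).labels
        a = treehmm.shuffle_control(fitted3, raster, labels, seed=20,
                                    n_shuffles=2)
        b = treehmm.shuffle_control(fitted3, raster, labels, seed=20,
                                    n_shuffles=2)
        np.testing.assert_allclose(a["dprime"], b["dprime"])


class TestClusterInformation:
    def test_constant_labels_zero_bits(self):
        assert treehmm.cluster_information([np.zeros(50, int)] * 4) == 0.0

    def test_deterministic_labels_give_log2_m_bits(self):
        labels = np.tile(np.arange(4), 25)  # equiprobable, bin-determined
        info = treehmm.cluster_information([labels] * 6)
        assert info == pytest.approx(2.0)

    def test_noisy_channel_matches_closed_form(self):
        # binary channel: true label by bin parity, flipped with prob eps
        rng = np.random.default_rng(21)
        eps, R, B = 0.1, 200, 400
        base = np.arange(B) % 2
        labs = [np.where(rng.random(B) < eps, 1 - base, base)
                for _ in range(R)]
        h2 = -(eps * np.log2(eps) + (1 - eps) * np.log2(1 - eps))
        expected = 1.0 - h2
        info = treehmm.cluster_information(labs)
        assert info == pytest.approx(expected, abs=0.05)


class TestSerialization:
    def test_hdf5_round_trip(self, fitted3, mode_raster, tmp_path):
        raster, _ = mode_raster
        path = tmp_path / "hmm.h5"
        fitted3.to_hdf5(path)
        back = TreeHMM.from_hdf5(path)
        assert back.log_likelihood(raster) == pytest.approx(
            fitted3.log_likelihood(raster))
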