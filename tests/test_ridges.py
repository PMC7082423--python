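"""Energy-landscape ascent, soft local maxima, ridgelines, membership."""

from itertools import combinations

import numpy as np
import pytest

import popglass as pg
from popglass import maxent, ridges, treehmm


class TestAscendFull:
    def test_all_negative_fields_descend_to_silence(self):
        m = maxent.MaxEntModel(np.full(6, -1.0), np.zeros((6, 6)))
        rng = np.random.default_rng(0)
        for k in range(5):
            start = (rng.random(6) < 0.5).astype(np.uint8)
            assert ridges.ascend_full(m, start, seed=k).sum() == 0

    def test_trajectory_probability_monotone(self, frustrated10):
        rng = np.random.default_rng(1)
        for k in range(10):
            start = (rng.random(10) < 0.3).astype(np.uint8)
            _, traj = ridges.ascend_full(frustrated10, start, seed=k,
                                         return_trajectory=True)
            assert np.all(np.diff(traj) > 0)

    def test_endpoint_is_true_flip_maximum(self, frustrated10):
        rng = np.random.default_rng(2)
        for k in range(10):
            start = (rng.random(10) < 0.3).astype(np.uint8)
            end = ridges.ascend_full(frustrated10, start, seed=k)
            # exhaustive neighbor check
            e0 = frustrated10.energy(end.astype(float))
            for i in range(10):
                nb = end.copy().astype(float)
                nb[i] = 1 - nb[i]
                assert frustrated10.energy(nb) >= e0 - 1e-10
            assert ridges.is_flip_local_max(frustrated10, end)

    def test_fixed_point_returned_unchanged(self, frustrated10):
        end = ridges.ascend_full(frustrated10, np.zeros(10, np.uint8), seed=3)
        again = ridges.ascend_full(frustrated10, end, seed=4)
        np.testing.assert_array_equal(end, again)


class TestAscendFixedK:
    def test_saturated_pattern_returned_immediately(self, frustrated6):
        start = np.ones(6, np.uint8)
        sm = ridges.ascend_fixed_K(frustrated6, start, 4, seed=5)
        np.testing.assert_array_equal(sm.pattern, start)
        assert sm.K == 6
        assert sm.robust

    def test_endpoint_is_true_swap_maximum(self):
        m = pg.make_frustrated_model(12, 0.7, -2.0, seed=41)
        rng = np.random.default_rng(6)
        for k in range(6):
            start = np.zeros(12, np.uint8)
            start[rng.choice(12, 4, replace=False)] = 1
            sm = ridges.ascend_fixed_K(m, start, 6, seed=k)
            assert sm.K == 4
            assert ridges.is_swap_local_max(m, sm.pattern)

    def test_determinism(self, frustrated10):
        start = np.zeros(10, np.uint8)
        start[:3] = 1
        a = ridges.ascend_fixed_K(frustrated10, start, 6, seed=7)
        b = ridges.ascend_fixed_K(frustrated10, start, 6, seed=7)
        np.testing.assert_array_equal(a.pattern, b.pattern)
        assert a.robustness == b.robustness

    def test_all_starts_reach_exactly_the_true_maxima(self):
        """Ascent endpoints from every K=3 start coincide with the
        enumerated set of swap-local maxima at K=3."""
        m = pg.make_frustrated_model(8, 0.8, -2.0, seed=42)
        true_maxima = set()
        for combo in combinations(range(8), 3):
            pat = np.zeros(8, np.uint8)
            pat[list(combo)] = 1
            if ridges.is_swap_local_max(m, pat):
                true_maxima.add(tuple(pat))
        endpoints = set()
        for k, combo in enumerate(combinations(range(8), 3)):
            pat = np.zeros(8, np.uint8)
            pat[list(combo)] = 1
            sm = ridges.ascend_fixed_K(m, pat, 4, seed=k)
            endpoints.add(tuple(sm.pattern))
        assert endpoints == true_maxima

    def test_needs_at_least_one_spike(self, frustrated6):
        with pytest.raises(ValueError):
            ridges.ascend_fixed_K(frustrated6, np.zeros(6, np.uint8))


class TestTraceRidgeline:
    def test_independent_model_yields_analytic_field_ordering(self):
        h = np.array([2.0, -1.0, -1.5, -2.0, -2.5, -3.0])
        m = maxent.MaxEntModel(h, np.zeros((6, 6)))
        start = np.zeros(6, np.uint8)
        start[0] = 1
        sm = ridges.ascend_fixed_K(m, start, 5, seed=1)
        chains = ridges.trace_ridgeline(m, sm, K_limit=4, seed=2, n_paths=5)
        assert len(chains) == 1
        got = [list(s.active) for s in chains[0].chain]
        assert got == [[0], [0, 1], [0, 1, 2], [0, 1, 2, 3]]

    def test_chain_members_differ_by_one_added_spike(self,
                                                     two_community_model):
        start = np.zeros(12, np.uint8)
        start[:2] = 1
        sm = ridges.ascend_fixed_K(two_community_model, start, 5, seed=3)
        for ridge in ridges.trace_ridgeline(two_community_model, sm,
                                            K_limit=6, seed=4, n_paths=5):
            for a, b in zip(ridge.chain[:-1], ridge.chain[1:]):
                assert b.K == a.K + 1
                assert np.all(b.pattern >= a.pattern)
                assert (b.pattern != a.pattern).sum() == 1

    def test_two_communities_give_disjoint_active_sets(self,
                                                       two_community_model):
        out = []
        for lo in (0, 6):
            start = np.zeros(12, np.uint8)
            start[lo:lo + 2] = 1
            sm = ridges.ascend_fixed_K(two_community_model, start, 5,
                                       seed=lo)
            ridge = ridges.trace_ridgeline(two_community_model, sm,
                                           K_limit=6, seed=5 + lo,
                                           n_paths=5)[0]
            out.append(set(ridge.active_set))
        assert out[0].isdisjoint(out[1])
        assert out[0] | out[1] == set(range(12))


class TestMembershipRule:
    @pytest.fixture()
    def ridge(self, two_community_model):
        start = np.zeros(12, np.uint8)
        start[:2] = 1
        sm = ridges.ascend_fixed_K(two_community_model, start, 5, seed=6)
        return ridges.trace_ridgeline(two_community_model, sm, K_limit=5,
                                      seed=7, n_paths=5)[0]

    def test_all_silent_pattern_excluded(self, ridge):
        assert not ridges.membership_rule(ridge)(np.zeros(12, np.uint8))

    def test_chain_members_included(self, ridge):
        rule = ridges.membership_rule(ridge)
        for sm in ridge.chain:
            assert rule(sm.pattern)

    def test_spike_outside_active_set_vetoes(self, ridge):
        rule = ridges.membership_rule(ridge)
        pat = ridge.chain[0].pattern.copy()
        pat[ridge.silent_set[0]] = 1
        assert not rule(pat)

    def test_count_above_k_max_excluded(self, ridge):
        pat = np.zeros(12, np.uint8)
        pat[ridge.active_set] = 1
        if ridge.active_set.size > ridge.K_max:
            assert not ridges.membership_rule(ridge)(pat)


class TestMatchRidgesToHmm:
    def test_planted_communities_match_modes_purely(self, two_community_model):
        raster = pg.sample_ising(two_community_model, 3000, seed=8)
        hmm_model = treehmm.fit(raster, 2, dict(n_restarts=2, max_iters=30),
                                seed=9)
        rls = []
        for lo in (0, 6):
            start = np.zeros(12, np.uint8)
            start[lo:lo + 2] = 1
            sm = ridges.ascend_fixed_K(two_community_model, start, 5,
                                       seed=10 + lo)
            rls.append(ridges.trace_ridgeline(two_community_model, sm,
                                              K_limit=5, seed=12 + lo,
                                              n_paths=5)[0])
        table = ridges.match_ridges_to_hmm(rls, hmm_model)
        assert {t["matched_mode"] for t in table} == {0, 1}
        assert all(t["purity"] == 1.0 for t in table)
        assert all(r.matched_mode is not None for r in rls)

    def test_serialization_round_trip(self, two_community_model, tmp_path):
        start = np.zeros(12, np.uint8)
        start[:2] = 1
        sm = ridges.ascend_fixed_K(two_community_model, start, 5, seed=14)
        rls = ridges.trace_ridgeline(two_community_model, sm, K_limit=5,
                                     seed=15, n_paths=5)
        path = tmp_path / "ridges.json"
        ridges.save_ridgelines(rls, path)
        import json
        data = json.loads(path.read_text())
        assert data[0]["K_min"] == rls[0].K_min
        assert data[0]["active_set"] == rls[0].active_set.tolist()
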