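"""Pairwise maximum-entropy inference: exact, Monte Carlo, and scaling."""

import numpy as np
import pytest

import popglass as pg
from popglass import maxent
from popglass.raster import PairwiseStats


def stats_from_model(model):
    """Exact moments of an enumerable model as PairwiseStats."""
    mean, m2, _ = maxent.exact_moments(model.h, model.J)
    return PairwiseStats(mean, m2, n_bins=10**6)


class TestEnergy:
    def test_all_silent_pattern_has_zero_energy(self, frustrated6):
        assert frustrated6.energy(np.zeros(6)) == 0.0

    def test_single_spike_energy_is_minus_field(self, frustrated6):
        pat = np.zeros(6)
        pat[2] = 1
        assert frustrated6.energy(pat) == pytest.approx(-frustrated6.h[2])

    def test_pair_energy_includes_coupling(self, frustrated6):
        pat = np.zeros(6)
        pat[1] = pat[4] = 1
        expect = -frustrated6.h[1] - frustrated6.h[4] - frustrated6.J[1, 4]
        assert frustrated6.energy(pat) == pytest.approx(expect)

    def test_distribution_normalizes(self, frustrated6):
        pats = maxent.enumerate_patterns(6)
        assert np.exp(frustrated6.log_probability(pats)).sum() == \
            pytest.approx(1.0, abs=1e-10)


class TestExactFit:
    def test_single_neuron_half_rate_gives_zero_field(self):
        s = PairwiseStats(np.array([0.5]), np.array([[0.5]]), 100)
        m = maxent.exact_fit(s)
        assert m.h[0] == pytest.approx(0.0, abs=1e-6)

    def test_two_neuron_closed_form_log_odds(self):
        # joint table p11=.25, p10=p01=.15, p00=.45
        p = np.array([0.40, 0.40])
        m2 = np.array([[0.40, 0.25], [0.25, 0.40]])
        m = maxent.exact_fit(PairwiseStats(p, m2, 1000))
        h_expect = np.log(0.15 / 0.45)
        j_expect = np.log(0.25 * 0.45 / (0.15 * 0.15))
        np.testing.assert_allclose(m.h, h_expect, atol=1e-5)
        assert m.J[0, 1] == pytest.approx(j_expect, abs=1e-5)

    def test_independent_targets_give_zero_couplings(self):
        p = np.array([0.2, 0.4, 0.3])
        m2 = np.outer(p, p)
        np.fill_diagonal(m2, p)
        m = maxent.exact_fit(PairwiseStats(p, m2, 1000))
        iu = np.triu_indices(3, 1)
        assert np.abs(m.J[iu]).max() < 1e-4

    def test_recovers_planted_parameters(self, frustrated6):
        m = maxent.exact_fit(stats_from_model(frustrated6), tol=1e-8)
        np.testing.assert_allclose(m.h, frustrated6.h, atol=1e-4)
        np.testing.assert_allclose(m.J, frustrated6.J, atol=1e-4)

    def test_infeasible_moments_rejected_naming_pair(self):
        p = np.array([0.2, 0.2])
        m2 = np.array([[0.2, 0.21], [0.21, 0.2]])  # m12 > min(p1, p2)
        with pytest.raises(ValueError, match=r"m\[0,1\]"):
            maxent.exact_fit(PairwiseStats(p, m2, 100))

    def test_entropy_not_below_empirical(self, raster6, stats6):
        """Maximum-entropy property on real sampled data."""
        model = maxent.exact_fit(stats6, tol=1e-6)
        model_bits = maxent.model_entropy_bits(model)
        census = pg.pattern_census(raster6)
        freq = np.array(list(census.values())) / raster6.n_bins
        empirical_bits = -(freq * np.log2(freq)).sum()
        assert model_bits >= empirical_bits - 1e-9


class TestMcFit:
    def test_determinism(self, stats6):
        cfg = dict(max_iters=60, min_iters=60, check_every=60, n_samples=300,
                   average_last=20, check_samples=2000)
        m1 = maxent.mc_fit(stats6, cfg, seed=5, raise_on_fail=False)
        m2 = maxent.mc_fit(stats6, cfg, seed=5, raise_on_fail=False)
        np.testing.assert_array_equal(m1.J, m2.J)
        np.testing.assert_array_equal(m1.h, m2.h)

    def test_null_data_yields_negligible_couplings(self):
        rng = np.random.default_rng(6)
        values = (rng.random((8, 20000)) < 0.2).astype(np.uint8)
        stats = pg.empirical_stats(pg.BinaryRaster(values))
        m = maxent.mc_fit(stats, dict(max_iters=400, min_iters=200,
                                      check_every=200), seed=7,
                          raise_on_fail=False)
        iu = np.triu_indices(8, 1)
        # couplings bounded by a few times the sampling noise of the moments
        se_j = 3.0 / (np.sqrt(20000) * 0.2 * 0.8)
        assert np.abs(m.J[iu]).mean() < 3 * se_j

    def test_agrees_with_exact_fit_at_n12(self):
        truth = pg.make_frustrated_model(12, 0.5, -2.0, seed=31)
        r = pg.sample_ising(truth, 50000, seed=32)
        stats = pg.empirical_stats(r)
        ex = maxent.exact_fit(stats, tol=1e-6)
        mc = maxent.mc_fit(stats, dict(max_iters=600, min_iters=300,
                                       check_every=300, init="pair"),
                           seed=33, raise_on_fail=False)
        iu = np.triu_indices(12, 1)
        assert np.corrcoef(mc.J[iu], ex.J[iu])[0, 1] > 0.95
        assert np.abs(mc.h - ex.h).max() < 0.25


class TestPseudoLikelihood:
    def test_agrees_with_exact_fit_on_sampled_data(self, frustrated10):
        raster = pg.sample_ising(frustrated10, 50000, seed=55)
        stats = pg.empirical_stats(raster)
        ex = maxent.exact_fit(stats, tol=1e-6)
        pl = maxent.pl_fit(raster.values)
        iu = np.triu_indices(10, 1)
        assert np.corrcoef(pl.J[iu], ex.J[iu])[0, 1] > 0.98
        slope = np.polyfit(ex.J[iu], pl.J[iu], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)
        assert np.abs(pl.h - ex.h).max() < 0.2

    def test_deterministic(self, raster6):
        a = maxent.pl_fit(raster6.values)
        b = maxent.pl_fit(raster6.values)
        np.testing.assert_array_equal(a.J, b.J)


class TestScaleCouplings:
    def test_factor_one_is_noop(self, frustrated6):
        s = stats_from_model(frustrated6)
        m = maxent.scale_couplings(frustrated6, 1.0, s)
        np.testing.assert_allclose(m.h, frustrated6.h, atol=1e-4)
        np.testing.assert_allclose(m.J, frustrated6.J)

    def test_factor_zero_gives_logit_fields(self, frustrated6):
        s = stats_from_model(frustrated6)
        m = maxent.scale_couplings(frustrated6, 0.0, s)
        np.testing.assert_allclose(
            m.h, np.log(s.rates / (1 - s.rates)), atol=1e-8)
        assert np.all(m.J == 0)

    def test_doubling_keeps_rates_and_strengthens_correlations(self,
                                                               frustrated6):
        s = stats_from_model(frustrated6)
        m = maxent.scale_couplings(frustrated6, 2.0, s)
        mean, m2, _ = maxent.exact_moments(m.h, m.J)
        np.testing.assert_allclose(mean, s.rates, atol=1e-5)
        iu = np.triu_indices(6, 1)
        cov_scaled = (m2 - np.outer(mean, mean))[iu]
        assert np.abs(cov_scaled).mean() > np.abs(s.covariance[iu]).mean()


class TestScaleCorrelations:
    def test_gamma_one_identity(self, stats6):
        out = maxent.scale_correlations(stats6, 1.0)
        np.testing.assert_allclose(out.second_moments, stats6.second_moments)

    def test_gamma_zero_factorizes(self, stats6):
        out = maxent.scale_correlations(stats6, 0.0)
        p = stats6.rates
        expect = np.outer(p, p)
        np.fill_diagonal(expect, p)
        np.testing.assert_allclose(out.second_moments, expect, atol=1e-12)

    def test_gamma_half_halves_covariance(self, stats6):
        out = maxent.scale_correlations(stats6, 0.5)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(out.covariance[off],
                                   0.5 * stats6.covariance[off], atol=1e-12)
        # variances are fixed by the (untouched) rates
        np.testing.assert_allclose(np.diag(out.covariance),
                                   np.diag(stats6.covariance))
        np.testing.assert_allclose(out.rates, stats6.rates)


class TestDegenerateNeurons:
    def test_silent_neuron_excluded_with_warning(self, caplog):
        values = np.array([[1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 0, 0]],
                          dtype=np.uint8)
        stats = pg.empirical_stats(pg.BinaryRaster(values))
        model = maxent.exact_fit(stats)
        assert model.n_neurons == 2
        np.testing.assert_array_equal(model.diagnostics["kept"], [0, 2])


class TestSerialization:
    def test_model_hdf5_round_trip(self, frustrated6, tmp_path):
        path = tmp_path / "m.h5"
        frustrated6.to_hdf5(path)
        back = maxent.MaxEntModel.from_hdf5(path)
        np.testing.assert_allclose(back.h, frustrated6.h)
        np.testing.assert_allclose(back.J, frustrated6.J)
        assert back.T == frustrated6.T
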