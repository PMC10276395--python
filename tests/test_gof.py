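import numpy as np
import pytest
from scipy import stats

from dipd.gof import (
    EntryAggregate,
    aggregate_entries,
    battery_accepts,
    dispersion_test,
    ks_poisson,
    poissoneity_battery,
    qq_envelope,
    zero_inflation_test,
)


def make_agg(counts, lambdas, lam0=None):
    counts = np.asarray(counts)
    lambdas = np.asarray(lambdas, dtype=float)
    return EntryAggregate(float(lam0 if lam0 is not None else lambdas.mean()),
                          None, counts, lambdas)


class TestAggregateEntries:
    def test_nearest_two_by_inspection(self):
        lam = np.array([[1.0, 2.0], [3.0, 4.0]])
        x = np.array([[10, 20], [30, 40]])
        agg = aggregate_entries(lam, x, lambda0=2.4, m=2)
        assert sorted(agg.lambdas.tolist()) == [2.0, 3.0]
        assert sorted(agg.counts.tolist()) == [20, 30]

    def test_exhaustive_when_m_equals_size(self):
        lam = np.arange(1, 7, dtype=float).reshape(2, 3)
        agg = aggregate_entries(lam, lam.astype(int), lambda0=3.0, m=6)
        assert len(agg) == 6

    def test_tie_breaks_to_lower_row_major_index(self):
        # |1-2| == |3-2|: entry (0,0) must win over (1,1)
        lam = np.array([[1.0, 10.0], [20.0, 3.0]])
        x = np.zeros((2, 2), dtype=int)
        agg = aggregate_entries(lam, x, lambda0=2.0, m=1)
        assert agg.entries.tolist() == [[0, 0]]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            aggregate_entries(np.ones((2, 2)), np.ones((2, 2), dtype=int), 1.0, m=5)


class TestKsPoisson:
    def test_quantile_sequence_gives_tiny_distance(self):
        lam0 = 4.0
        probs = (np.arange(1, 201) - 0.5) / 200
        x = stats.poisson.ppf(probs, lam0).astype(int)
        agg = make_agg(x, np.full(200, lam0), lam0)
        d, p = ks_poisson(agg)
        assert d < 0.05 and p > 0.5

    def test_all_zeros_against_rate_five(self):
        agg = make_agg(np.zeros(100, dtype=int), np.full(100, 5.0), 5.0)
        d, _ = ks_poisson(agg)
        assert d == pytest.approx(1 - np.exp(-5), abs=1e-12)

    def test_conservative_under_null(self):
        rng = np.random.default_rng(17)
        lam = np.full(200, 2.0)
        rej = sum(
            ks_poisson(make_agg(rng.poisson(lam), lam, 2.0)).p_value < 0.05
            for _ in range(500)
        )
        assert rej / 500 <= 0.05

    def test_single_rate_reference_matches_when_rates_equal(self):
        rng = np.random.default_rng(2)
        lam = np.full(150, 3.0)
        agg = make_agg(rng.poisson(lam), lam, 3.0)
        a = ks_poisson(agg)
        b = ks_poisson(agg, use_entry_rates=False)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


class TestDispersionTest:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        lam = np.full(200, 2.0)
        rej = sum(
            dispersion_test(make_agg(rng.poisson(lam), lam)).p_value < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rej / 1000 <= 0.07

    def test_power_against_negative_binomial(self):
        # Var = 2 * mean: NB with size = mean
        rng = np.random.default_rng(8)
        n, mean = 10_000, 2.0
        lam = np.full(n, mean)
        hits = sum(
            dispersion_test(
                make_agg(rng.negative_binomial(mean, 0.5, n), lam)
            ).p_value < 0.05
            for _ in range(60)
        )
        assert hits / 60 > 0.95

    def test_underdispersed_constant_sample(self):
        agg = make_agg(np.full(50, 2), np.full(50, 2.0))
        res = dispersion_test(agg)
        assert res.alpha_hat < 0 and res.p_value > 0.5

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 30"):
            dispersion_test(make_agg(np.ones(10, dtype=int), np.ones(10)))

    def test_mixture_of_rates_detected_more_at_larger_m(self):
        """Rates spanning [lam0/2, 2*lam0] trigger rejections; fewer at m=100."""
        rng = np.random.default_rng(9)
        lam0 = 2.0
        span = np.exp(np.linspace(np.log(lam0 / 2), np.log(2 * lam0), 200))
        central = np.sort(np.argsort(np.abs(span - lam0), kind="stable")[:100])
        hit200 = hit100 = 0
        reps = 400
        for _ in range(reps):
            x = rng.poisson(span)
            hit200 += dispersion_test(
                make_agg(x, np.full(200, lam0), lam0)).p_value < 0.05
            hit100 += dispersion_test(
                make_agg(x[central], np.full(100, lam0), lam0)).p_value < 0.05
        assert hit200 / reps > 0.8
        assert hit100 < hit200


class TestZeroInflationTest:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(10)
        lam = rng.uniform(0.5, 4.0, 200)
        rej = sum(
            zero_inflation_test(make_agg(rng.poisson(lam), lam)).p_value < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rej / 1000 <= 0.07

    def test_power_against_structural_zeros(self):
        rng = np.random.default_rng(11)
        lam = np.full(200, 2.0)
        hits = 0
        for _ in range(400):
            x = rng.poisson(lam)
            x[rng.random(200) < 0.2] = 0
            hits += zero_inflation_test(make_agg(x, lam)).p_value < 0.05
        assert hits / 400 > 0.9

    def test_expected_zero_fraction_formula(self):
        lam = np.array([0.5, 1.0, 2.0, 4.0])
        res = zero_inflation_test(make_agg([0, 0, 1, 2], lam))
        assert res.expected == pytest.approx(np.exp(-lam).mean())
        assert res.var_pi == pytest.approx(
            np.sum(np.exp(-lam) * (1 - np.exp(-lam))) / 16)

    def test_no_zeros_observed_is_not_inflation(self):
        res = zero_inflation_test(make_agg(np.ones(50, dtype=int) * 3,
                                           np.full(50, 5.0)))
        assert res.z < 0 and res.p_value > 0.5

    def test_degenerate_when_zeros_impossible(self):
        res = zero_inflation_test(make_agg(np.full(40, 800), np.full(40, 800.0)))
        assert res.degenerate and res.p_value == 1.0


class TestQqEnvelope:
    def test_null_sample_mostly_inside_band(self):
        rng = np.random.default_rng(12)
        lam = np.full(200, 3.0)
        good = 0
        for i in range(40):
            agg = make_agg(rng.poisson(lam), lam, 3.0)
            env = qq_envelope(agg, n_sim=200, seed=i)
            good += env.fraction_inside >= 0.9
        assert good / 40 >= 0.9

    def test_overdispersed_sample_exits_above(self):
        rng = np.random.default_rng(13)
        lam0 = 2.0
        agg = make_agg(rng.poisson(4 * lam0, 200), np.full(200, lam0), lam0)
        env = qq_envelope(agg, n_sim=200, seed=0)
        upper_exits = env.observed[-20:] > env.upper[-20:]
        assert upper_exits.any() and not env.inside

    def test_band_stabilizes_with_simulations(self):
        rng = np.random.default_rng(14)
        lam = np.full(200, 5.0)
        agg = make_agg(rng.poisson(lam), lam, 5.0)
        e500 = qq_envelope(agg, n_sim=500, seed=1)
        e1000 = qq_envelope(agg, n_sim=1000, seed=2)
        assert np.abs(e500.lower - e1000.lower).max() <= 1
        assert np.abs(e500.upper - e1000.upper).max() <= 1

    def test_too_few_simulations_rejected(self):
        agg = make_agg(np.zeros(10, dtype=int), np.full(10, 1.0))
        with pytest.raises(ValueError):
            qq_envelope(agg, n_sim=5)


class TestBattery:
    def test_jointly_nonsignificant_on_true_rates(self, homogeneous_with_rates):
        """On counts drawn at the estimated rates, the three tests of one
        aggregate are jointly non-significant in at least 85% of replicates."""
        from dipd.gof import gof_report

        m, _, rates = homogeneous_with_rates
        rng = np.random.default_rng(15)
        ok = 0
        for i in range(40):
            rep = gof_report(rng.poisson(rates), rates, 0.5,
                             seed=i, with_envelope=False)
            ok += (rep.ks.p_value >= 0.05
                   and rep.dispersion.p_value >= 0.05
                   and rep.zero_inflation.p_value >= 0.05)
        assert ok / 40 >= 0.85

    def test_full_battery_accepts_true_rates(self, homogeneous_with_rates):
        """Familywise-controlled battery accepts a correctly specified model."""
        m, _, rates = homogeneous_with_rates
        rng = np.random.default_rng(16)
        ok = sum(battery_accepts(rng.poisson(rates), rates, seed=i)
                 for i in range(40))
        assert ok / 40 >= 0.85

    def test_report_has_one_row_per_in_range_target(self, homogeneous_with_rates):
        m, _, rates = homogeneous_with_rates
        df = poissoneity_battery(m.values, rates, lambda0_grid=(0.1, 0.5, 1e9))
        assert df["lambda0"].tolist() == [0.1, 0.5]
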