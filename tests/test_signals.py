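"""Disproportionality statistics against hand arithmetic and oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, special

from faerspv import signals as sg
from faerspv.signals import ContingencyTable as CT


class TestBuildContingency:
    def test_toy_hand_count(self, toy_store):
        t = sg.build_contingency(toy_store, "drugx", ["Proteinuria"])
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)

    def test_empty_target_pts(self, toy_store):
        t = sg.build_contingency(toy_store, "drugx", [])
        assert t.a == 0 and t.c == 0

    def test_absent_drug_gives_zero_margin(self, toy_store):
        t = sg.build_contingency(toy_store, "nosuchdrug", ["Proteinuria"])
        assert t.a == 0 and t.b == 0

    def test_vectorized_matches_single(self, small_store):
        frame = sg.contingency_all(small_store, ["Proteinuria"])
        for drug in list(frame.index)[:8]:
            t = sg.build_contingency(small_store, drug, ["Proteinuria"])
            row = frame.loc[drug]
            assert (t.a, t.b, t.c, t.d) == tuple(row[["a", "b", "c", "d"]])

    def test_exact_ground_truth_counts(self, small_cohort, small_store):
        _, _, truth = small_cohort
        frame = sg.contingency_all(small_store, ["Proteinuria"])
        for drug, a_true in truth.ps_event_counts.items():
            assert frame.loc[drug, "a"] == a_true


class TestFrequentist:
    def test_independence_table(self):
        t = CT(10, 10, 10, 10)
        ror, lo, hi = sg.ror_with_ci(t)
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi
        prr, chi2 = sg.prr_chi2(t)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        e, rr = sg.expected_count(t)
        assert (e, rr) == (pytest.approx(10.0), pytest.approx(1.0))

    def test_small_table_hand_arithmetic(self):
        t = CT(2, 1, 1, 2)
        prr, chi2 = sg.prr_chi2(t)
        assert prr == pytest.approx(2.0)
        assert chi2 == pytest.approx(2.0 / 3.0)
        e, rr = sg.expected_count(t)
        assert e == pytest.approx(1.5)
        assert rr == pytest.approx(4.0 / 3.0)

    def test_zero_cell_continuity_correction(self):
        t = CT(1, 0, 1, 1)
        assert np.isnan(sg.ror_with_ci(t)[0])
        ror, _, _ = sg.ror_with_ci(t, zero_correction=True)
        assert ror == pytest.approx(3.0)

    def test_chi2_zero_iff_ad_equals_bc(self):
        assert sg.prr_chi2(CT(4, 2, 6, 3))[1] == pytest.approx(0.0)
        assert sg.prr_chi2(CT(5, 2, 6, 3))[1] > 0

    def test_zero_drug_margin_flagged_missing(self):
        prr, chi2 = sg.prr_chi2(CT(0, 0, 5, 5))
        assert np.isnan(prr)

    @given(st.integers(1, 500), st.integers(1, 500),
           st.integers(1, 500), st.integers(1, 500))
    def test_oracle_equivalence(self, a, b, c, d):
        """ROR/PRR/chi2/E match plain arithmetic on random tables."""
        t = CT(a, b, c, d)
        n = a + b + c + d
        assert sg.ror_with_ci(t)[0] == pytest.approx(a * d / (b * c), rel=1e-12)
        prr, chi2 = sg.prr_chi2(t)
        assert prr == pytest.approx((a / (a + b)) / (c / (c + d)), rel=1e-12)
        expect_chi2 = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(expect_chi2, rel=1e-12)
        assert sg.expected_count(t)[0] == pytest.approx((a + b) * (a + c) / n,
                                                        rel=1e-12)


class TestBcpnn:
    def test_ic_zero_at_independence(self):
        ic, _ = sg.bcpnn_ic(CT(10, 10, 10, 10))
        assert ic == pytest.approx(0.0)

    def test_noren_offset_at_a_250(self):
        t = CT(250, 100, 400, 10000)
        ic, ic025 = sg.bcpnn_ic(t)
        assert ic - ic025 == pytest.approx(3.3 / np.sqrt(250) + 2 / 250 ** 1.5)
        assert ic - ic025 == pytest.approx(0.20921, abs=1e-4)

    def test_a_zero_missing(self):
        assert np.isnan(sg.bcpnn_ic(CT(0, 10, 10, 10))[0])

    def test_bate_mode_shrinks_toward_null_and_agrees_asymptotically(self):
        ic0, _ = sg.bcpnn_ic(CT(100, 100, 100, 100), mode="bate")
        assert ic0 == pytest.approx(0.0, abs=0.05)
        t = sg.reconstruct_table(738, 16355, 41.01, 39.68)
        ic_mle, _ = sg.bcpnn_ic(t, mode="mle")
        ic_bate, ic025_bate = sg.bcpnn_ic(t, mode="bate")
        assert ic025_bate < ic_bate < ic_mle  # Bayesian estimate pulls to 0
        assert ic_bate == pytest.approx(ic_mle, rel=0.02)


class TestReconstruct:
    def test_forward_example(self):
        t = sg.reconstruct_table(10, 20, 4.0, 2.5)
        assert (t.a, t.b, t.c, t.d) == (10, 10, 10, 40)

    @given(st.integers(2, 200), st.integers(1, 300),
           st.integers(1, 300), st.integers(1, 5000))
    def test_round_trip_inverts_exactly(self, a, b, c, d):
        t = CT(a, b, c, d)
        ror = sg.ror_with_ci(t)[0]
        prr = sg.prr_chi2(t)[0]
        if not np.isfinite(ror) or abs(ror - prr) < 1e-9:
            return
        back = sg.reconstruct_table(a, a + c, ror, prr)
        assert back.b == pytest.approx(b, rel=1e-9)
        assert back.d == pytest.approx(d, rel=1e-9)

    def test_equal_ror_prr_rejected(self):
        with pytest.raises(ValueError, match="non-reconstructible"):
            sg.reconstruct_table(10, 100, 2.0, 2.0)

    def test_a_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sg.reconstruct_table(100, 100, 3.0, 2.0)


class TestMgps:
    def test_likelihood_not_worse_than_classic_init(self):
        rng = np.random.default_rng(1)
        e = rng.lognormal(0.5, 1.0, 5000)
        a = rng.poisson(rng.gamma(1.5, 1.0, 5000) * e)
        prior = sg.fit_mgps_hyperprior(a, e, seed=1)
        init = np.array([np.log(0.2), np.log(0.1), np.log(2.0), np.log(4.0),
                         special.logit(1 / 3)])
        assert prior.loglik >= sg._mixture_loglik(init, a, e) - 1e-6

    def test_degenerate_unit_rate_prior_mean_near_one(self):
        rng = np.random.default_rng(2)
        e = rng.lognormal(1.0, 1.0, 20000)
        a = rng.poisson(e)  # lambda = 1 exactly
        prior = sg.fit_mgps_hyperprior(a, e, seed=2)
        assert 0.9 < prior.mean < 1.1

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            sg.fit_mgps_hyperprior([1, 2], [1.0, 0.0])


class TestEbgm:
    PRIOR = sg.GammaMixturePrior(0.5, 0.5, 2.0, 4.0, 0.4)

    def test_single_component_closed_form(self):
        prior = sg.GammaMixturePrior(2.0, 4.0, 2.0, 4.0, 0.5)
        ebgm, _ = sg.ebgm_scores(0, 1e-12, prior)
        assert ebgm == pytest.approx(np.exp(special.digamma(2.0)) / 4.0, rel=1e-9)

    def test_shrinkage_vanishes_at_large_counts(self):
        ebgm, ebgm05 = sg.ebgm_scores(73800, 1945.4, self.PRIOR)
        assert ebgm == pytest.approx(73800 / 1945.4, rel=2e-3)
        assert ebgm05 <= ebgm

    def test_monotone_in_a(self):
        values = [sg.ebgm_scores(a, 10.0, self.PRIOR)[0] for a in (5, 10, 20, 40)]
        assert values == sorted(values)

    def test_shrinks_toward_prior_mean(self):
        ebgm, _ = sg.ebgm_scores(30, 10.0, self.PRIOR)  # a/E above prior mean
        assert ebgm <= 3.0

    def test_quantile_matches_quadrature(self):
        """Bisection EBGM05 agrees with numerical integration of the
        posterior density on random (a, E, prior) triples."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            prior = sg.GammaMixturePrior(
                rng.uniform(0.2, 3), rng.uniform(0.2, 3),
                rng.uniform(0.5, 4), rng.uniform(0.5, 4), rng.uniform(0.2, 0.8))
            a = int(rng.integers(0, 50))
            e = rng.uniform(0.5, 30)
            _, q05 = sg.ebgm_scores(a, e, prior)
            qw, (s1, r1), (s2, r2) = sg.posterior_mixture(a, e, prior)

            def pdf(x):
                from scipy.stats import gamma
                return (qw * gamma.pdf(x, s1, scale=1 / r1)
                        + (1 - qw) * gamma.pdf(x, s2, scale=1 / r2))

            mass, _ = integrate.quad(pdf, 0, q05, limit=200)
            assert mass == pytest.approx(0.05, abs=1e-6)


class TestFlags:
    def make_stats(self, table, prior=None):
        return sg.compute_signal_stats("x", table, prior=prior)

    def test_independence_all_false(self):
        flags = self.make_stats(CT(10, 10, 10, 10),
                                sg.GammaMixturePrior(0.5, 0.5, 2, 4, 0.4)).flags
        assert not any(flags[k] for k in ("ror", "prr", "bcpnn", "mgps", "consensus"))

    def test_small_a_blocks_ror_flag(self):
        s = self.make_stats(CT(2, 1, 20, 4000))
        assert s.ror > 100
        assert not s.flags["ror"]

    def test_strong_signal_all_true(self):
        t = sg.reconstruct_table(738, 16355, 41.01, 39.68)
        prior = sg.GammaMixturePrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
        s = self.make_stats(t, prior)
        assert s.flags["consensus"]

    def test_missing_component_not_evaluable(self):
        s = sg.compute_signal_stats("x", CT(0, 5, 10, 100))
        assert not s.flags["consensus"]
        assert "ror" in s.flags["not_evaluable"]
        assert "mgps" in s.flags["not_evaluable"]
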