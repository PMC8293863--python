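import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import binom, norm

from evidfn import (
    EvidenceDesign,
    bernoulli_closed_forms,
    evidential_rates,
    misspecified_rates,
    np_alpha_prime,
    np_beta,
    np_beta_prime,
    np_design,
    peak_misleading,
    postdata_misleading,
    sigma_case_classifier,
)
from evidfn.clt import np_alpha, np_log_critical_value

Z05 = norm.ppf(0.95)


def exact_tail(p1, p2, pg, n, cutoff, upper=False):
    """Enumeration oracle: P(logLR <= cutoff) (or >=) under Binomial(n, pg)."""
    a, b = math.log(p1 / p2), math.log((1 - p1) / (1 - p2))
    s = np.arange(n + 1)
    loglr = s * a + (n - s) * b
    pmf = binom.pmf(s, n, pg)
    return float(pmf[loglr >= cutoff].sum() if upper else pmf[loglr <= cutoff].sum())


class TestNPCriticalValue:
    def test_median_alpha(self, ds_misspec):
        assert np_log_critical_value(ds_misspec, 0.5, 50) == pytest.approx(
            50 * ds_misspec.K12, abs=1e-12
        )

    def test_plugin_value_and_exact_size(self, ds_misspec):
        ds = ds_misspec
        logc = np_log_critical_value(ds, 0.05, 100)
        assert logc == pytest.approx(100 * ds.K12 - 10 * ds.sigma1 * Z05, abs=1e-12)
        assert logc == pytest.approx(5.257, abs=2e-3)
        # calibration collapse, and realized size by enumeration under f1
        assert np_alpha(ds, logc, 100) == pytest.approx(0.05, abs=1e-12)
        assert exact_tail(0.75, 0.50, 0.75, 100, logc) == pytest.approx(0.05, abs=0.03)

    def test_per_observation_limit(self, ds_misspec):
        vals = [np_log_critical_value(ds_misspec, 0.05, n) / n for n in (10, 10**3, 10**6)]
        gaps = [abs(v - ds_misspec.K12) for v in vals]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3

    def test_degenerate_sigma(self):
        ds = bernoulli_closed_forms(0.6, 0.6, 0.5)
        with pytest.raises(ValueError):
            np_log_critical_value(ds, 0.05, 10)


class TestNPBeta:
    def test_vanishes_with_n(self, ds_misspec):
        b = [np_beta(ds_misspec, 0.05, n) for n in (10, 100, 1000)]
        assert b[0] > b[1] > b[2]
        assert b[2] < 1e-6

    def test_zero_effect_size(self):
        # nearly identical candidates: beta approaches 1 − alpha
        ds = bernoulli_closed_forms(0.6, 0.6 - 1e-6, 0.5)
        assert np_beta(ds, 0.05, 100) == pytest.approx(0.95, abs=1e-3)

    def test_against_enumeration(self, ds_misspec):
        ds = ds_misspec
        logc = np_log_critical_value(ds, 0.05, 25)
        exact = exact_tail(0.75, 0.50, 0.50, 25, logc, upper=False)
        assert np_beta(ds, 0.05, 25) == pytest.approx(1.0 - exact, abs=0.03)


class TestMisspecifiedNP:
    def test_collapse_to_alpha(self, ds_correct):
        assert np_alpha_prime(ds_correct, 0.05, 37) == pytest.approx(0.05, abs=1e-12)

    def test_worked_value(self, ds_misspec):
        assert np_alpha_prime(ds_misspec, 0.05, 100) == pytest.approx(0.727, abs=1e-3)

    def test_monotone_to_one(self, ds_misspec):
        vals = [np_alpha_prime(ds_misspec, 0.05, n) for n in (10, 50, 100, 500, 5000)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.999

    def test_precondition_routing(self, ds_misspec):
        flipped = bernoulli_closed_forms(0.75, 0.50, 0.40)
        with pytest.raises(ValueError):
            np_alpha_prime(flipped, 0.05, 10)
        with pytest.raises(ValueError):
            np_beta_prime(ds_misspec, 0.05, 10)

    def test_beta_prime_collapse_and_limit(self):
        ds = bernoulli_closed_forms(0.75, 0.50, 0.50)  # g identical to f2
        for n in (10, 80):
            assert np_beta_prime(ds, 0.05, n) == pytest.approx(
                np_beta(ds, 0.05, n), abs=1e-12
            )
        assert np_beta_prime(ds, 0.05, 4000) < 1e-9

    def test_beta_prime_against_enumeration(self):
        ds = bernoulli_closed_forms(0.75, 0.50, 0.40)
        logc = np_log_critical_value(ds, 0.05, 50)
        exact = exact_tail(0.75, 0.50, 0.40, 50, logc, upper=False)
        assert np_beta_prime(ds, 0.05, 50) == pytest.approx(1.0 - exact, abs=0.03)

    def test_sigma_case_classifier(self, ds_misspec, ds_correct):
        rep = sigma_case_classifier(ds_misspec, "alpha", 0.05, 100)
        assert rep.case == "negative"  # sigma1 < sigma_g for this triple
        assert rep.exceeds_nominal  # consistent with alpha'(100) = 0.73 > 0.05
        rep0 = sigma_case_classifier(ds_correct, "alpha", 0.05, 100)
        assert rep0.case == "zero" and not rep0.exceeds_nominal
        repb = sigma_case_classifier(
            bernoulli_closed_forms(0.75, 0.50, 0.40), "beta", 0.05, 50
        )
        assert repb.case in ("positive", "zero", "negative")
        assert repb.exceeds_nominal == (repb.primed > repb.nominal)


class TestEvidentialRates:
    def test_degenerate_threshold(self, ds_correct):
        ds = ds_correct
        rec = evidential_rates(ds, EvidenceDesign(1.0 + 1e-12), 40)
        assert rec.W1 == pytest.approx(0.0, abs=1e-9)
        assert rec.M1 == pytest.approx(
            norm.cdf(-math.sqrt(40) * ds.K12 / ds.sigma1), abs=1e-9
        )

    def test_invalid_design(self):
        with pytest.raises(ValueError):
            EvidenceDesign(0.9)
        with pytest.raises(ValueError):
            EvidenceDesign(8.0, 1.5)

    def test_all_rates_vanish(self, ds_correct):
        rec = evidential_rates(ds_correct, EvidenceDesign(8.0), 5000)
        for q in ("M1", "W1", "M2", "W2"):
            assert getattr(rec, q) < 1e-8
        assert rec.V1 > 1 - 1e-8

    def test_monotone_totals_and_v_dominance(self, ds_correct):
        design = EvidenceDesign(8.0)
        totals, vs = [], []
        for n in (1, 5, 20, 80, 320, 1280):
            rec = evidential_rates(ds_correct, design, n)
            totals.append(rec.M1 + rec.W1)
            vs.append(rec.V1)
            assert rec.V1 > rec.M1
        assert all(b < a for a, b in zip(totals, totals[1:]))
        assert all(b > a for a, b in zip(vs, vs[1:]))


class TestMisspecifiedRates:
    def test_collapse_when_g_is_f1(self, ds_correct):
        design = EvidenceDesign(8.0)
        for n in (3, 30, 300):
            mis = misspecified_rates(ds_correct, design, n)
            cor = evidential_rates(ds_correct, design, n)
            assert mis.M1 == pytest.approx(cor.M1, abs=1e-12)
            assert mis.W1 == pytest.approx(cor.W1, abs=1e-12)

    def test_symmetry_and_its_breaking(self, ds_misspec):
        sym = misspecified_rates(ds_misspec, EvidenceDesign(8.0), 60)
        assert sym.M1 == sym.M2 and sym.W1 == sym.W2
        asym = misspecified_rates(ds_misspec, EvidenceDesign(8.0, 1 / 20), 60)
        assert asym.M1 != asym.M2

    def test_equal_quality_limits(self):
        from evidfn import equidistant_pg

        ds = bernoulli_closed_forms(0.75, 0.50, equidistant_pg(0.75, 0.50))
        design = EvidenceDesign(8.0)
        m_prev = 0.0
        for n in (10, 100, 10**4, 10**6):
            rec = misspecified_rates(ds, design, n)
            assert rec.M1 > m_prev  # no interior peak: climbs toward 1/2
            m_prev = rec.M1
        assert rec.M1 == pytest.approx(0.5, abs=2e-3)
        assert rec.W1 == pytest.approx(0.0, abs=4e-3)


class TestPeakMisleading:
    def test_worked_peak_location(self, ds_misspec):
        res = peak_misleading(EvidenceDesign(8.0), ds_misspec.K12, ds_misspec.sigma1)
        assert res.n_peak == pytest.approx(15.90, abs=0.01)
        assert res.interior

    def test_matches_numeric_maximum(self, ds_misspec):
        k, drift, sd = EvidenceDesign(8.0), ds_misspec.K12, ds_misspec.sigma1

        def neg_m(n):
            return -norm.cdf(-(math.log(8.0) / math.sqrt(n) + math.sqrt(n) * drift) / sd)

        opt = minimize_scalar(neg_m, bounds=(1.0, 1e4), method="bounded",
                              options={"xatol": 1e-10})
        res = peak_misleading(k, drift, sd)
        assert res.M_peak == pytest.approx(-opt.fun, abs=1e-10)

    def test_scaling_invariance(self):
        d = EvidenceDesign(8.0)
        base = peak_misleading(d, 0.13, 0.5).M_peak
        for c in (0.25, 4.0, 9.0):
            scaled = peak_misleading(d, c * 0.13, math.sqrt(c) * 0.5).M_peak
            assert scaled == pytest.approx(base, abs=1e-12)

    def test_zero_drift(self):
        res = peak_misleading(EvidenceDesign(8.0), 0.0, 0.5)
        assert not res.interior and math.isinf(res.n_peak)
        assert res.limit == 0.5


class TestPostdataMisleading:
    def test_equals_pre_data_at_threshold(self, ds_misspec):
        ds, n, k = ds_misspec, 40, 8.0
        rec = evidential_rates(ds, EvidenceDesign(k), n)
        p1, p2, _ = postdata_misleading(ds, -math.log(k), n)
        assert p1 == pytest.approx(rec.M1, abs=1e-12)
        assert p2 == pytest.approx(rec.M2, abs=1e-12)

    def test_typical_value_is_median(self, ds_misspec):
        p1, _, _ = postdata_misleading(ds_misspec, 30 * ds_misspec.K12, 30)
        assert p1 == pytest.approx(0.5, abs=1e-12)

    def test_against_enumeration(self, ds_misspec):
        p1, _, _ = postdata_misleading(ds_misspec, 1.0, 30)
        assert p1 == pytest.approx(exact_tail(0.75, 0.50, 0.75, 30, 1.0), abs=0.03)

    def test_severity_complements_p2(self, ds_misspec):
        _, p2, sev = postdata_misleading(ds_misspec, 2.3, 50)
        assert sev == 1.0 - p2
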