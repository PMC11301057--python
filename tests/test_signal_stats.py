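"""Disproportionality statistics against independent oracles and their
order/sign invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy.integrate import quad
from scipy.special import digamma
from scipy.stats import gamma as gamma_dist
from scipy.stats import nbinom

from aers_signal import signal_stats as ss
from aers_signal.signal_stats import ContingencyTable as CT


def toy_event_rows():
    """Cohort reports with PT sets {X},{X,Y},{Y}; background {X},{Y},{Y},{Z},{Z}."""
    rows = []
    for pid, pts in [
        ("1", ["X"]), ("2", ["X", "Y"]), ("3", ["Y"]),
        ("4", ["X"]), ("5", ["Y"]), ("6", ["Y"]), ("7", ["Z"]), ("8", ["Z"]),
    ]:
        rows += [(pid, p, "SOC_A") for p in pts]
    return pd.DataFrame(rows, columns=["primaryid", "pt", "soc"])


class TestBuildTables:
    def test_hand_enumerated_toy_database(self):
        # 9 unique (report, PT) pairs; 4 in the cohort. For X: a=2 cohort
        # pairs, b=4-2=2, c=1 background X pair, d=9-2-2-1=4.
        tables = ss.build_tables(toy_event_rows(), {"1", "2", "3"}, "PT")
        t = tables["X"]
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 4)

    def test_cohort_pair_total_constant(self):
        tables = ss.build_tables(toy_event_rows(), {"1", "2", "3"}, "PT")
        totals = {t.a + t.b for t in tables.values()}
        assert totals == {4}

    def test_term_margins_partition_N(self):
        rows = toy_event_rows()
        tables = ss.build_tables(rows, {"1", "2", "3"}, "PT")
        # Z has a=0 so is absent from the output; reconstruct its margin.
        covered = sum(t.a + t.c for t in tables.values())
        assert covered + 2 == 9  # two Z pairs + covered margins = all pairs

    def test_only_terms_with_cohort_cases_returned(self):
        tables = ss.build_tables(toy_event_rows(), {"1", "2", "3"}, "PT")
        assert "Z" not in tables

    def test_soc_level_counts_report_once(self):
        rows = toy_event_rows()
        tables = ss.build_tables(rows, {"1", "2", "3"}, "SOC")
        t = tables["SOC_A"]
        assert t.a == 3 and t.N == 8  # every report counted once at SOC level

    def test_empty_event_table(self):
        empty = pd.DataFrame(columns=["primaryid", "pt", "soc"])
        assert ss.build_tables(empty, set(), "PT") == {}


class TestRorPrr:
    def test_ror_cross_product(self):
        r = ss.ror_stat(CT(10, 90, 100, 9900))
        assert r.ror == pytest.approx(11.0)

    def test_symmetric_table_is_null(self):
        r = ss.ror_stat(CT(5, 5, 5, 5))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_zero_cell_non_evaluable(self):
        assert ss.ror_stat(CT(0, 5, 5, 5)) is None
        assert ss.ror_stat(CT(5, 5, 5, 0)) is None

    def test_prr_ratio(self):
        r = ss.prr_stat(CT(10, 90, 100, 9900))
        assert r.prr == pytest.approx(10.0)

    def test_independence_table(self):
        r = ss.prr_stat(CT(10, 90, 100, 900))  # ad = bc
        assert r.prr == pytest.approx(1.0)
        assert r.chi2 == pytest.approx(0.0)

    def test_yates_correction_shrinks_chi2(self):
        plain = ss.prr_stat(CT(10, 90, 100, 9900)).chi2
        corrected = ss.prr_stat(CT(10, 90, 100, 9900), yates=True).chi2
        assert corrected < plain


def random_tables(n, seed, a_min=1):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        a = int(rng.integers(a_min, 200))
        b = int(rng.integers(1, 3000))
        c = int(rng.integers(1, 3000))
        d = int(rng.integers(1000, 500000))
        out.append(CT(a, b, c, d))
    return out


class TestIndependentOracles:
    """ROR/PRR/χ² against statsmodels and scipy; the implementations must
    agree with the independent routes to 1e-9 relative."""

    def test_ror_prr_chi2_against_reference_libraries(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        from scipy.stats import chi2_contingency

        for t in random_tables(50, seed=7):
            table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
            sm = sm_ct.Table2x2(table)
            r = ss.ror_stat(t)
            assert r.ror == pytest.approx(sm.oddsratio, rel=1e-9)
            # log-normal CI with the conventional 1.96 multiplier, built
            # from statsmodels' independent standard error
            lo = math.exp(sm.log_oddsratio - 1.96 * sm.log_oddsratio_se)
            hi = math.exp(sm.log_oddsratio + 1.96 * sm.log_oddsratio_se)
            assert r.ci_low == pytest.approx(lo, rel=1e-9)
            assert r.ci_high == pytest.approx(hi, rel=1e-9)
            p = ss.prr_stat(t)
            assert p.prr == pytest.approx(sm.riskratio, rel=1e-9)
            chi2 = chi2_contingency(table, correction=False).statistic
            assert p.chi2 == pytest.approx(chi2, rel=1e-9)


class TestBcpnn:
    def test_independence_ic_near_zero(self):
        ic = ss.bcpnn_ic(CT(100, 9900, 9900, 980100))
        assert -0.1 < ic.ic < 0.1

    def test_ic025_strictly_below_expectation(self):
        for t in random_tables(20, seed=3):
            ic = ss.bcpnn_ic(t)
            assert ic.ic025 < ic.ic

    def test_monte_carlo_posterior_agreement(self):
        # posterior sampling of the underlying beta model; the closed form
        # carries an O(1/a) approximation gap, well under 0.05 bits at the
        # case counts where the criteria can fire
        t = CT(50, 450, 500, 49000)
        rng = np.random.default_rng(11)
        n = 10**6
        N, a, ab, ac = t.N, t.a, t.a + t.b, t.a + t.c
        g = (N + 2) * (N + 2) / ((ab + 1) * (ac + 1))
        p1 = rng.beta(ab + 1, N - ab + 1, n)
        p2 = rng.beta(ac + 1, N - ac + 1, n)
        p11 = rng.beta(a + 1, N - a + g - 1, n)
        mc = float(np.mean(np.log2(p11 / (p1 * p2))))
        assert ss.bcpnn_ic(t).ic == pytest.approx(mc, abs=0.05)


def posterior_mixture(t, prior):
    E = t.expected
    l1 = nbinom.logpmf(t.a, prior.alpha1, prior.beta1 / (prior.beta1 + E))
    l2 = nbinom.logpmf(t.a, prior.alpha2, prior.beta2 / (prior.beta2 + E))
    w1 = prior.w * math.exp(l1)
    w2 = (1 - prior.w) * math.exp(l2)
    q1 = w1 / (w1 + w2)
    g1 = gamma_dist(a=prior.alpha1 + t.a, scale=1.0 / (prior.beta1 + E))
    g2 = gamma_dist(a=prior.alpha2 + t.a, scale=1.0 / (prior.beta2 + E))
    return q1, g1, g2


class TestEbgm:
    def test_single_component_closed_form(self):
        # w=1, a=5, E=1, Gamma(2,4) prior: EBGM = exp(psi(7))/5
        t = CT(5, 5, 5, 85)
        assert t.expected == pytest.approx(1.0)
        prior = ss.MgpsPrior(2.0, 4.0, 2.0, 4.0, 1.0)
        r = ss.ebgm_stat(t, prior)
        assert r.ebgm == pytest.approx(math.exp(digamma(7)) / 5, rel=1e-12)

    def test_quadrature_oracle_mixture(self):
        t = CT(10, 90, 100, 9900)
        prior = ss.MgpsPrior(0.5, 0.3, 3.0, 2.0, 0.4)
        r = ss.ebgm_stat(t, prior)
        q1, g1, g2 = posterior_mixture(t, prior)
        val, _ = quad(
            lambda x: math.log(x) * (q1 * g1.pdf(x) + (1 - q1) * g2.pdf(x)),
            1e-12, 200, limit=200,
        )
        assert r.ebgm == pytest.approx(math.exp(val), abs=1e-6)
        mass, _ = quad(lambda x: q1 * g1.pdf(x) + (1 - q1) * g2.pdf(x), 0, r.eb05, limit=200)
        assert mass == pytest.approx(0.05, abs=1e-6)

    def test_data_overwhelm_prior(self):
        t = CT(10000, 10000, 90000, 9000000)
        E = t.expected
        prior = ss.MgpsPrior(*ss.DUMOUCHEL_START)
        r = ss.ebgm_stat(t, prior)
        assert 0.95 * (t.a / E) <= r.ebgm <= 1.05 * (t.a / E)

    def test_eb05_below_ebgm(self):
        prior = ss.MgpsPrior(*ss.DUMOUCHEL_START)
        for t in random_tables(20, seed=5):
            r = ss.ebgm_stat(t, prior)
            assert r.eb05 < r.ebgm


class _Cell:
    """Minimal (a, E) view used to feed the hyperparameter fit directly."""

    def __init__(self, a, expected):
        self.a = a
        self.expected = expected


class TestMgpsFit:
    def simulate(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        E = np.exp(rng.uniform(np.log(0.5), np.log(50), n))
        lam = rng.gamma(2.0, 1.0 / 4.0, n)
        a = rng.poisson(lam * E)
        return [_Cell(int(x), float(e)) for x, e in zip(a, E)]

    def test_parameter_recovery_single_gamma(self):
        # counts simulated from lambda ~ Gamma(2, rate 4); the dominant
        # fitted component must recover (2, 4) within 25%
        prior = ss.fit_mgps_prior(self.simulate(seed=0))
        comps = [(prior.w, prior.alpha1, prior.beta1), (1 - prior.w, prior.alpha2, prior.beta2)]
        _, alpha, beta = max(comps)
        assert abs(alpha - 2.0) / 2.0 < 0.25
        assert abs(beta - 4.0) / 4.0 < 0.25

    def test_improves_on_published_start(self):
        cells = self.simulate(seed=1)
        prior = ss.fit_mgps_prior(cells)
        a = np.array([c.a for c in cells], float)
        E = np.array([c.expected for c in cells], float)

        def loglik(a1, b1, a2, b2, w):
            l1 = nbinom.logpmf(a, a1, b1 / (b1 + E))
            l2 = nbinom.logpmf(a, a2, b2 / (b2 + E))
            return float(np.logaddexp(np.log(w) + l1, np.log(1 - w) + l2).sum())

        assert prior.loglik >= loglik(*ss.DUMOUCHEL_START) - 1e-6
        assert prior.loglik == pytest.approx(
            loglik(prior.alpha1, prior.beta1, prior.alpha2, prior.beta2, prior.w), abs=1e-6
        )

    def test_weight_in_unit_interval(self):
        prior = ss.fit_mgps_prior(self.simulate(seed=2))
        assert 0.0 <= prior.w <= 1.0

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ss.fit_mgps_prior([_Cell(0, 1.0), _Cell(0, 2.0)])


@given(
    a=hst.integers(1, 50),
    b=hst.integers(1, 500),
    c=hst.integers(1, 500),
    d=hst.integers(1, 50000),
)
def test_sign_consistency_ror_prr(a, b, c, d):
    t = CT(a, b, c, d)
    ror = ss.ror_stat(t).ror
    prr = ss.prr_stat(t).prr
    s = np.sign(a * d - b * c)
    assert np.sign(np.round(ror - 1, 12)) == s
    assert np.sign(np.round(prr - 1, 12)) == s


def test_monotone_in_a_for_fixed_margins():
    """Holding a+b, a+c and N fixed, every statistic is non-decreasing in a."""
    ab, ac, N = 100, 150, 10000
    prior = ss.MgpsPrior(*ss.DUMOUCHEL_START)
    prev = None
    for a in range(1, 100):
        t = CT(a, ab - a, ac - a, N - ab - ac + a)
        cur = (
            ss.ror_stat(t).ror,
            ss.prr_stat(t).prr,
            ss.bcpnn_ic(t).ic,
            ss.ebgm_stat(t, prior).ebgm,
        )
        if prev is not None:
            assert all(x >= p - 1e-12 for x, p in zip(cur, prev))
        prev = cur


class TestCriteriaAndScreen:
    def test_strong_table_all_flags(self):
        tables = {"X": CT(10, 90, 100, 9900)}
        prior = ss.MgpsPrior(*ss.DUMOUCHEL_START)
        t = tables["X"]
        res = ss.SignalResult(
            "PT", "X", "SOC_A", t,
            ror=ss.ror_stat(t), prr=ss.prr_stat(t), ic=ss.bcpnn_ic(t),
            ebgm=ss.ebgm_stat(t, prior),
        )
        ss.evaluate_criteria(res)
        assert res.flags == {"ROR": True, "PRR": True, "BCPNN": True, "MGPS": True}
        assert res.retained

    def test_min_case_gate(self):
        t = CT(2, 8, 10, 1000)
        res = ss.SignalResult("PT", "X", "S", t, ror=ss.ror_stat(t), prr=ss.prr_stat(t),
                              ic=ss.bcpnn_ic(t))
        ss.evaluate_criteria(res)
        assert not res.flags["ROR"] and not res.flags["PRR"]

    def test_exact_independence_all_flags_false(self):
        t = CT(10, 90, 100, 900)
        prior = ss.MgpsPrior(*ss.DUMOUCHEL_START)
        res = ss.SignalResult("PT", "X", "S", t, ror=ss.ror_stat(t), prr=ss.prr_stat(t),
                              ic=ss.bcpnn_ic(t), ebgm=ss.ebgm_stat(t, prior))
        ss.evaluate_criteria(res)
        assert not any(res.flags.values()) and not res.retained

    def test_any_k_retention_rule(self):
        t = CT(10, 90, 100, 9900)
        prior = ss.MgpsPrior(*ss.DUMOUCHEL_START)
        res = ss.SignalResult("PT", "X", "S", t, ror=ss.ror_stat(t), prr=ss.prr_stat(t),
                              ic=ss.bcpnn_ic(t), ebgm=ss.ebgm_stat(t, prior))
        ss.evaluate_criteria(res, ss.ScreenConfig(retention=1))
        assert res.retained

    def test_screen_output_contract(self, fixture_events, fixture_cohort):
        cohort, _ = fixture_cohort
        ids = {r.primaryid for r in cohort}
        results = ss.screen(fixture_events, ids, "PT")
        tables = ss.build_tables(fixture_events, ids, "PT")
        assert len(results) == len(tables)
        for r in results:
            if r.retained:
                assert all(r.flags.values())
        socs = [r.soc for r in results]
        assert socs == sorted(socs)
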