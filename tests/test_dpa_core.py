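"""Disproportionality statistics against independent oracles, plus the
positivity rule."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, optimize, special, stats

from pvsignal.cohort_builder import ContingencyTable
from pvsignal.dpa_core import (MGPS_INITIAL, MgpsHyperParameters,
                               SignalCriteria, SignalStatistics,
                               _mixture_loglik, classify_signal,
                               compute_bcpnn, compute_chi2, compute_ebgm,
                               compute_prr, compute_ror, ebgm_arrays,
                               fit_mgps, statistics_frame)

tables_st = st.builds(ContingencyTable,
                      a=st.integers(1, 500), b=st.integers(1, 5000),
                      c=st.integers(1, 5000), d=st.integers(1, 100000))


def _stats_from(ror=5.0, prr=5.0, chi2=100.0, ic025=1.0, ebgm05=5.0, a=100):
    return SignalStatistics(a=a, expected=1.0, ror=ror, ror_lo=ror, ror_hi=ror,
                            prr=prr, prr_lo=prr, prr_hi=prr, chi2=chi2,
                            ic=ic025 + 1, ic025=ic025, ebgm=ebgm05 + 1,
                            ebgm05=ebgm05)


class TestRor:
    def test_independence_table_gives_one(self):
        assert compute_ror(ContingencyTable(10, 90, 100, 900))[0] == \
            pytest.approx(1.0)

    def test_worked_example(self):
        ror, lo, hi = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert lo == pytest.approx(11.0 * math.exp(-1.959963984540054 * se))
        assert hi == pytest.approx(11.0 * math.exp(+1.959963984540054 * se))

    def test_zero_cell_yields_nan_marker(self):
        ror, lo, hi = compute_ror(ContingencyTable(0, 10, 10, 100))
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)

    def test_continuity_correction_makes_zero_cell_finite(self):
        ror, lo, hi = compute_ror(ContingencyTable(0, 10, 10, 100),
                                  continuity=True)
        assert ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))
        assert lo < ror < hi

    @given(tables_st)
    def test_interval_brackets_point_estimate(self, t):
        ror, lo, hi = compute_ror(t)
        assert lo <= ror <= hi


class TestPrr:
    def test_independence_table_gives_one(self):
        assert compute_prr(ContingencyTable(10, 90, 100, 900))[0] == \
            pytest.approx(1.0)

    def test_worked_example(self):
        assert compute_prr(ContingencyTable(10, 90, 100, 9900))[0] == \
            pytest.approx(10.0)

    @given(tables_st)
    def test_permutation_symmetry(self, t):
        """prr(a,b,c,d) == 1/prr(c,d,a,b)."""
        fwd = compute_prr(t)[0]
        rev = compute_prr(ContingencyTable(t.c, t.d, t.a, t.b))[0]
        assert fwd == pytest.approx(1.0 / rev, rel=1e-12)


class TestChi2:
    def test_independence_is_zero_both_variants(self):
        t = ContingencyTable(10, 90, 100, 900)
        assert compute_chi2(t, yates=False) == pytest.approx(0.0)
        assert compute_chi2(t, yates=True) == pytest.approx(0.0)

    def test_worked_example_uncorrected(self):
        assert compute_chi2(ContingencyTable(10, 90, 100, 9900),
                            yates=False) == pytest.approx(74.447, abs=0.001)

    def test_agrees_with_scipy(self):
        t = ContingencyTable(17, 83, 211, 9689)
        obs = [[t.a, t.b], [t.c, t.d]]
        for yates in (True, False):
            ref = stats.chi2_contingency(obs, correction=yates)[0]
            assert compute_chi2(t, yates=yates) == pytest.approx(ref, rel=1e-12)

    @given(tables_st)
    def test_transpose_invariance(self, t):
        tt = ContingencyTable(t.a, t.c, t.b, t.d)
        assert compute_chi2(t) == pytest.approx(compute_chi2(tt), rel=1e-12)

    def test_degenerate_margin_is_nan(self):
        assert math.isnan(compute_chi2(ContingencyTable(0, 0, 5, 5)))


class TestBcpnn:
    def test_zero_a_with_large_margins_is_negative(self):
        ic, ic025 = compute_bcpnn(ContingencyTable(0, 1000, 1000, 100000))
        assert ic < 0

    def test_near_zero_at_exact_independence_large_n(self):
        # a equals its expectation: 100 = 10000 * 10000 / 1000000
        t = ContingencyTable(100, 9900, 9900, 980100)
        ic, ic025 = compute_bcpnn(t)
        assert abs(ic) < 0.05
        assert ic025 < ic

    def test_agrees_with_mean_of_log_oracle(self):
        """The closed form uses log-of-posterior-means; an independent
        mean-of-logs computation over the same Beta/Dirichlet posteriors
        (via digamma) must agree closely for non-tiny counts."""
        for (a, b, c, d) in [(50, 450, 500, 9000), (120, 880, 2000, 47000),
                             (30, 70, 300, 700)]:
            t = ContingencyTable(a, b, c, d)
            ic, _ = compute_bcpnn(t)
            n = t.n
            cx, cy, cxy = a + b, a + c, a
            g = (n + 2) * (n + 2) / ((cx + 1) * (cy + 1))
            psi = special.digamma
            e_log = (psi(cxy + 1) - psi(n + g)
                     - (psi(cx + 1) - psi(n + 2))
                     - (psi(cy + 1) - psi(n + 2))) / math.log(2)
            assert ic == pytest.approx(e_log, abs=0.05)

    @given(tables_st)
    def test_lower_bound_below_point_estimate(self, t):
        ic, ic025 = compute_bcpnn(t)
        assert ic025 < ic


class TestMgpsFit:
    def test_parameter_recovery_single_gamma(self):
        rng = np.random.default_rng(3)
        lam = rng.gamma(2.0, 1 / 4.0, 5000)
        e = rng.uniform(0.5, 20, 5000)
        a = rng.poisson(lam * e)
        fit = fit_mgps((a, e))
        p = fit.params
        w1 = p.w
        comps = [(w1, p.alpha1, p.beta1), (1 - w1, p.alpha2, p.beta2)]
        w, alpha, beta = max(comps)
        assert w >= 0.9
        assert alpha == pytest.approx(2.0, rel=0.25)
        assert beta == pytest.approx(4.0, rel=0.25)

    def test_duplicated_cells_give_equivalent_fit(self):
        """Duplicating every cell doubles the log-likelihood and leaves the
        implied shrinkage unchanged.  Raw hyper-parameters are compared via
        the EBGM values they produce, because on near-null data the
        likelihood has a flat ridge along which they are unidentifiable."""
        rng = np.random.default_rng(4)
        e = rng.uniform(0.5, 10, 400)
        a = rng.poisson(1.0 * e)
        f1 = fit_mgps((a, e))
        f2 = fit_mgps((np.concatenate([a, a]), np.concatenate([e, e])))
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-6)
        for probe_a, probe_e in [(0, 1.0), (5, 2.0), (20, 4.0), (7, 7.0)]:
            e1 = compute_ebgm((probe_a, probe_e), f1.params)[0]
            e2 = compute_ebgm((probe_a, probe_e), f2.params)[0]
            assert e2 == pytest.approx(e1, rel=1e-3)

    def test_loglik_not_worse_than_initial_values(self):
        rng = np.random.default_rng(5)
        e = rng.uniform(0.5, 10, 300)
        a = rng.poisson(2.0 * e)
        fit = fit_mgps((a, e))
        x0 = np.array([math.log(MGPS_INITIAL[0]), math.log(MGPS_INITIAL[1]),
                       math.log(MGPS_INITIAL[2]), math.log(MGPS_INITIAL[3]),
                       special.logit(MGPS_INITIAL[4])])
        assert fit.loglik >= _mixture_loglik(x0, a.astype(float), e)

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError):
            fit_mgps(([3.0], [1.0]))


PARAMS = MgpsHyperParameters(0.8, 0.5, 2.0, 4.0, 0.4)


def _ebgm_quadrature(a, e, p):
    """Oracle: adaptive quadrature over the explicit posterior mixture."""
    w = np.array([p.w, 1 - p.w])
    shapes = np.array([p.alpha1 + a, p.alpha2 + a])
    rates = np.array([p.beta1 + e, p.beta2 + e])
    marg = w * stats.nbinom.pmf(a, [p.alpha1, p.alpha2],
                                [p.beta1 / (p.beta1 + e),
                                 p.beta2 / (p.beta2 + e)])
    q = marg / marg.sum()

    def pdf(lam):
        return sum(qi * stats.gamma.pdf(lam, s, scale=1 / r)
                   for qi, s, r in zip(q, shapes, rates))

    upper = float(max(stats.gamma.ppf(1 - 1e-12, s, scale=1 / r)
                      for s, r in zip(shapes, rates)))
    mean_log = integrate.quad(lambda x: math.log(x) * pdf(x), 0, upper,
                              limit=200)[0]
    ebgm = math.exp(mean_log)
    cdf = lambda x: sum(qi * stats.gamma.cdf(x, s, scale=1 / r)
                        for qi, s, r in zip(q, shapes, rates))
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, 1e-12, upper,
                             xtol=1e-10)
    return ebgm, ebgm05


class TestEbgm:
    def test_single_component_digamma_closed_form(self):
        p = MgpsHyperParameters(2.0, 4.0, 2.0, 4.0, 0.5)
        for a, e in [(0, 1.0), (7, 3.0), (40, 10.0)]:
            ebgm, _ = compute_ebgm((a, e), p)
            closed = math.exp(special.digamma(2 + a) - math.log(4 + e))
            assert ebgm == pytest.approx(closed, abs=1e-6)

    def test_matches_quadrature_oracle(self):
        for a, e in [(0, 0.5), (3, 1.0), (12, 4.0), (80, 90.0)]:
            ebgm, ebgm05 = compute_ebgm((a, e), PARAMS)
            o_ebgm, o_ebgm05 = _ebgm_quadrature(a, e, PARAMS)
            assert ebgm == pytest.approx(o_ebgm, abs=1e-6)
            assert ebgm05 == pytest.approx(o_ebgm05, abs=1e-6)

    def test_large_observed_equal_expected_shrinks_to_one(self):
        diffuse = MgpsHyperParameters(1.0, 1.0, 1.0, 1.0, 0.5)
        ebgm, _ = compute_ebgm((5000, 5000.0), diffuse)
        assert ebgm == pytest.approx(1.0, abs=0.01)

    def test_quantile_below_geometric_mean(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = int(rng.integers(0, 100))
            e = float(rng.uniform(0.2, 50))
            ebgm, ebgm05 = compute_ebgm((a, e), PARAMS)
            assert ebgm05 < ebgm

    def test_shrinkage_monotone_in_count_at_fixed_ratio(self):
        """With a/E fixed at 2, EBGM rises toward 2 as evidence grows."""
        values = [compute_ebgm((a, a / 2.0), PARAMS)[0]
                  for a in (2, 8, 32, 128, 512)]
        assert values == sorted(values)
        assert values[-1] == pytest.approx(2.0, abs=0.1)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 60, 25)
        e = rng.uniform(0.3, 40, 25)
        eb, eb05 = ebgm_arrays(a, e, PARAMS)
        for i in range(25):
            s_eb, s_eb05 = compute_ebgm((int(a[i]), float(e[i])), PARAMS)
            assert eb[i] == pytest.approx(s_eb, abs=1e-9)
            assert eb05[i] == pytest.approx(s_eb05, abs=1e-6)


class TestClassification:
    def test_printed_blood_lymphatic_row_is_positive(self):
        s = _stats_from(ror=6.58, prr=5.99, chi2=18220.09, ic025=2.53,
                        ebgm05=5.81, a=4325)
        assert classify_signal(s).positive

    def test_printed_psychiatric_row_is_negative(self):
        s = _stats_from(ror=0.34, prr=0.35, chi2=1098.47, ic025=-1.59,
                        ebgm05=0.34, a=877)
        cls = classify_signal(s)
        assert not cls.positive
        assert "ror" in cls.reasons

    def test_exact_thresholds_fail_strict_ebgm05(self):
        """ROR and PRR thresholds are inclusive but EBGM05 must strictly
        exceed 2, so a row sitting exactly on every threshold is negative."""
        s = _stats_from(ror=3.0, prr=2.0, ic025=0.5, ebgm05=2.0, a=10)
        cls = classify_signal(s)
        assert not cls.positive
        assert cls.reasons == ("ebgm05",)

    def test_nan_statistic_is_not_evaluable(self):
        s = _stats_from(ror=float("nan"))
        cls = classify_signal(s)
        assert not cls.positive
        assert cls.reasons == ("not evaluable",)

    def test_a_min_gate(self):
        s = _stats_from(a=2)
        assert not classify_signal(s).positive
        assert classify_signal(s, SignalCriteria(a_min=None)).positive

    def test_require_any_mode(self):
        s = _stats_from(ror=10.0, prr=1.0, ic025=-1.0, ebgm05=1.0)
        assert not classify_signal(s).positive
        assert classify_signal(s, SignalCriteria(require_all=False)).positive

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match="ror_min"):
            SignalCriteria(ror_min=-1.0)


def test_statistics_frame_matches_scalar_path():
    tables = {"E1": ContingencyTable(30, 70, 300, 9600),
              "E2": ContingencyTable(3, 97, 500, 9400),
              "E3": ContingencyTable(0, 100, 250, 9650)}
    frame = statistics_frame(tables, PARAMS)
    row = frame.set_index("label").loc["E1"]
    t = tables["E1"]
    assert row["ror"] == pytest.approx(compute_ror(t)[0])
    assert row["prr"] == pytest.approx(compute_prr(t)[0])
    assert row["chi2"] == pytest.approx(compute_chi2(t))
    assert row["ic025"] == pytest.approx(compute_bcpnn(t)[1])
    assert row["ebgm"] == pytest.approx(compute_ebgm(t, PARAMS)[0], abs=1e-9)
    zero_row = frame.set_index("label").loc["E3"]
    assert zero_row["signal"] == "negative"
    assert zero_row["reasons"] == "not evaluable"
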