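"""The four disproportionality statistics and the signal-positivity rule.

All four methods start from the 2×2 table (a, b, c, d) of one drug–event
pair against the rest of the database, N = a+b+c+d, and the expected count
under independence E = (a+b)(a+c)/N.

Frequentist statistics
----------------------
Reporting odds ratio (ROR)::

    ROR = (a·d) / (b·c)
    95% CI = exp( ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d) )

Proportional reporting ratio (PRR)::

    PRR = [a/(a+b)] / [c/(c+d)]
    95% CI = exp( ln PRR ± 1.96·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)) )

Pearson chi-square (Yates-corrected by default)::

    χ² = N·(|ad − bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)]   (Yates)
    χ² = N·(ad − bc)²        / [(a+b)(c+d)(a+c)(b+d)]    (uncorrected)

Zero cells make the ROR/PRR Wald intervals undefined; the default policy
returns NaN markers (such rows classify as "not evaluable"), and an optional
Haldane–Anscombe continuity correction (+0.5 to every cell) is available.

Bayesian confidence propagation neural network (BCPNN)
------------------------------------------------------
The information component IC = log2 p(drug, event)/(p(drug)·p(event)) is
estimated with the closed-form Dirichlet/Beta posterior approximation of the
original BCPNN formulation.  With c_x = a+b, c_y = a+c, c_xy = a and the
expectation-matched priors α1 = β1 = 1, α = β = 2, γ11 = 1,
γ = γ11·(N+α)(N+β) / [(c_x+α1)(c_y+β1)]  (chosen so the prior IC is 0)::

    IC    = log2[ (c_xy+γ11)(N+α)(N+β) / ((N+γ)(c_x+α1)(c_y+β1)) ]
    V(IC) = (1/ln 2)² · [ (N−c_xy+γ−γ11)/((c_xy+γ11)(1+N+γ))
                         + (N−c_x+α−α1)/((c_x+α1)(1+N+α))
                         + (N−c_y+β−β1)/((c_y+β1)(1+N+β)) ]
    IC025 = IC − 2·sqrt(V(IC))

Multi-item gamma Poisson shrinker (MGPS / EBGM)
-----------------------------------------------
The observed counts a are modelled as Poisson(λ·E) with the relative
reporting rate λ drawn from a two-component gamma mixture prior
w·Gamma(α1, β1) + (1−w)·Gamma(α2, β2) (shape/rate).  The marginal of a is
then a mixture of negative binomials; the five hyperparameters are fit by
maximizing the summed log marginal likelihood over all drug–event cells,
starting from the conventional initial values (0.2, 0.1, 2.0, 4.0, 1/3).
The posterior of λ given a is again a two-gamma mixture with components
Gamma(α_i+a, β_i+E) and weights ∝ w_i·NB(a; α_i, β_i/(β_i+E)); EBGM is the
posterior geometric mean 2^{E[log2 λ|a]} = exp(Σ_i Q_i(ψ(α_i+a) − ln(β_i+E)))
with ψ the digamma function, and EBGM05 the posterior 5th percentile,
solved numerically on the λ scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .cohort_builder import ContingencyTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: Conventional MGPS starting values (alpha1, beta1, alpha2, beta2, w).
MGPS_INITIAL = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)

# BCPNN expectation-matched prior constants.
_BC_A1 = _BC_B1 = 1.0   # Beta priors on p(drug), p(event)
_BC_A = _BC_B = 2.0
_BC_G11 = 1.0


@dataclass(frozen=True)
class SignalStatistics:
    """All four statistics (with interval bounds) for one 2×2 table."""

    a: int
    expected: float
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds of the positivity rule.

    Defaults encode the common four-algorithm rule: at least ``a_min``
    reports, ROR ≥ 3, PRR ≥ 2, EBGM05 > 2 and IC025 > 0, all required
    simultaneously.  Any threshold can be disabled by setting it to None.
    """

    ror_min: float | None = 3.0
    prr_min: float | None = 2.0
    ebgm05_min: float | None = 2.0
    ic025_min: float | None = 0.0
    a_min: int | None = 3
    require_all: bool = True

    def __post_init__(self) -> None:
        for name in ("ror_min", "prr_min", "ebgm05_min", "ic025_min", "a_min"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class SignalClassification:
    positive: bool
    #: reason codes for a negative call ("not evaluable" when NaN statistics
    #: prevented evaluation, otherwise the names of the failed thresholds)
    reasons: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return "positive" if self.positive else "negative"

    def __bool__(self) -> bool:
        return self.positive


# ---------------------------------------------------------------------------
# Frequentist statistics
# ---------------------------------------------------------------------------

def _cells(t: ContingencyTable, continuity: bool) -> tuple[float, float, float, float]:
    if continuity and 0 in (t.a, t.b, t.c, t.d):
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5
    return float(t.a), float(t.b), float(t.c), float(t.d)


def compute_ror(t: ContingencyTable,
                continuity: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% Wald interval.

    A zero cell without the continuity correction yields (nan, nan, nan).
    """
    a, b, c, d = _cells(t, continuity)
    if 0 in (a, b, c, d):
        return (math.nan,) * 3
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


def compute_prr(t: ContingencyTable,
                continuity: bool = False) -> tuple[float, float, float]:
    """Proportional reporting ratio with its 95% Wald interval."""
    a, b, c, d = _cells(t, continuity)
    if a == 0 or c == 0 or (a + b) == 0 or (c + d) == 0:
        return (math.nan,) * 3
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return (prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se))


def compute_chi2(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the 2×2 table; NaN if any margin is zero."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        return math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    return n * diff * diff / math.prod(margins)


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------

def compute_bcpnn(t: ContingencyTable) -> tuple[float, float]:
    """Information component and its 2-sigma lower bound (IC, IC025).

    Uses the closed-form posterior-moment approximation documented in the
    module header; defined for zero cells.
    """
    n = float(t.n)
    cx, cy, cxy = float(t.a + t.b), float(t.a + t.c), float(t.a)
    g = _BC_G11 * (n + _BC_A) * (n + _BC_B) / ((cx + _BC_A1) * (cy + _BC_B1))
    ic = math.log2((cxy + _BC_G11) * (n + _BC_A) * (n + _BC_B)
                   / ((n + g) * (cx + _BC_A1) * (cy + _BC_B1)))
    vic = ((n - cxy + g - _BC_G11) / ((cxy + _BC_G11) * (1 + n + g))
           + (n - cx + _BC_A - _BC_A1) / ((cx + _BC_A1) * (1 + n + _BC_A))
           + (n - cy + _BC_B - _BC_B1) / ((cy + _BC_B1) * (1 + n + _BC_B))
           ) / (math.log(2) ** 2)
    return ic, ic - 2.0 * math.sqrt(vic)


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MgpsHyperParameters:
    """The five parameters of the two-gamma mixture prior (shape/rate)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixture weight w must lie strictly in (0, 1)")


@dataclass(frozen=True)
class MgpsFit:
    """Result of an MGPS hyperparameter fit."""

    params: MgpsHyperParameters
    loglik: float
    converged: bool
    n_cells: int
    message: str = ""


class MgpsConvergenceError(RuntimeError):
    """Optimizer did not converge; carries the best parameters found."""

    def __init__(self, fit: MgpsFit):
        super().__init__(f"MGPS fit did not converge: {fit.message}")
        self.fit = fit


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float,
               e: np.ndarray) -> np.ndarray:
    # marginal of Poisson(λE), λ ~ Gamma(alpha, beta): NB(alpha, beta/(beta+E))
    return stats.nbinom.logpmf(a, alpha, beta / (beta + e))


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    # log w, log(1-w) via log-sigmoid: stable as the weight nears a boundary
    lw, l1w = special.log_expit(theta[4]), special.log_expit(-theta[4])
    lp = np.logaddexp(lw + _nb_logpmf(a, a1, b1, e),
                      l1w + _nb_logpmf(a, a2, b2, e))
    return float(np.sum(lp))


def fit_mgps(tables) -> MgpsFit:
    """Fit the five MGPS hyperparameters over all drug–event cells.

    ``tables`` may be a mapping label -> :class:`ContingencyTable`, an
    iterable of tables, or a pair of arrays ``(a, E)``.  Optimization is
    quasi-Newton (L-BFGS-B) on log-transformed gamma parameters and a
    logit-transformed weight, from the conventional starting values.
    """
    a, e = _as_counts(tables)
    if len(a) < 2:
        raise ValueError("MGPS fit needs at least 2 cells")

    x0 = np.array([math.log(MGPS_INITIAL[0]), math.log(MGPS_INITIAL[1]),
                   math.log(MGPS_INITIAL[2]), math.log(MGPS_INITIAL[3]),
                   special.logit(MGPS_INITIAL[4])])
    neg = lambda th: -_mixture_loglik(th, a, e)
    # Box bounds on the transformed scale: when one mixture component is
    # superfluous the weight drifts to a boundary along a flat likelihood
    # ridge; the bounds pin it at a negligible (< 1e-5) weight instead of
    # letting the optimizer chase an improvement that never materializes.
    bounds = [(-10.0, 10.0)] * 5
    converged = False
    with np.errstate(over="ignore", invalid="ignore"):
        # Quasi-Newton with restarts.  On near-null data the likelihood has
        # a flat ridge toward a point-mass prior (alpha, beta jointly large
        # at fixed alpha/beta); line searches can stall there, so a failed
        # round is followed by a bounded derivative-free polish and a
        # quasi-Newton restart from the polished point.
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-12, "gtol": 1e-8,
                                         "maxiter": 1000})
        converged = bool(res.success)
        for _ in range(3):
            if converged:
                break
            polish = optimize.minimize(neg, np.clip(res.x, -10.0, 10.0),
                                       method="Nelder-Mead", bounds=bounds,
                                       options={"fatol": 1e-9, "xatol": 1e-4,
                                                "maxfev": 4000})
            retry = optimize.minimize(neg, np.clip(polish.x, -10.0, 10.0),
                                      method="L-BFGS-B", bounds=bounds,
                                      options={"ftol": 1e-12, "gtol": 1e-8,
                                               "maxiter": 1000})
            best = min((polish, retry), key=lambda r: r.fun)
            improvement = res.fun - best.fun
            if best.fun <= res.fun:
                res = best
            # converged if the quasi-Newton restart is clean, the polish
            # terminated, or nothing beyond the loglik tolerance remains
            converged = (bool(retry.success) or bool(polish.success)
                         or improvement <= 1e-8)
    x = np.clip(res.x, -10.0, 10.0)
    a1, b1, a2, b2 = np.exp(x[:4])
    w = float(special.expit(x[4]))
    fit = MgpsFit(params=MgpsHyperParameters(a1, b1, a2, b2, w),
                  loglik=-float(res.fun), converged=converged,
                  n_cells=len(a), message=str(res.message))
    if not fit.converged:
        raise MgpsConvergenceError(fit)
    return fit


def _as_counts(tables) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(tables, tuple) and len(tables) == 2 \
            and not isinstance(tables[0], ContingencyTable):
        a = np.asarray(tables[0], dtype=float)
        e = np.asarray(tables[1], dtype=float)
        return a, e
    if hasattr(tables, "values"):
        tables = list(tables.values())
    else:
        tables = list(tables)
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    return a, e


def _posterior_weights(a: float, e: float,
                       th: MgpsHyperParameters) -> tuple[float, float]:
    l1 = math.log(th.w) + float(_nb_logpmf(np.array(a), th.alpha1, th.beta1,
                                           np.array(e)))
    l2 = math.log1p(-th.w) + float(_nb_logpmf(np.array(a), th.alpha2, th.beta2,
                                              np.array(e)))
    m = max(l1, l2)
    q1 = math.exp(l1 - m)
    q2 = math.exp(l2 - m)
    s = q1 + q2
    return q1 / s, q2 / s


def compute_ebgm(t: ContingencyTable | tuple[float, float],
                 params: MgpsHyperParameters) -> tuple[float, float]:
    """EBGM (posterior geometric mean of λ) and EBGM05 (posterior 5th pct).

    Accepts either a contingency table or a raw ``(a, E)`` pair.
    """
    if isinstance(t, ContingencyTable):
        a, e = float(t.a), t.expected
    else:
        a, e = float(t[0]), float(t[1])
    if e <= 0:
        raise ValueError("expected count E must be positive")
    q1, q2 = _posterior_weights(a, e, params)
    s1, r1 = params.alpha1 + a, params.beta1 + e
    s2, r2 = params.alpha2 + a, params.beta2 + e
    mean_log = (q1 * (special.digamma(s1) - math.log(r1))
                + q2 * (special.digamma(s2) - math.log(r2)))
    ebgm = math.exp(mean_log)

    def cdf(lam: float) -> float:
        return (q1 * stats.gamma.cdf(lam, s1, scale=1.0 / r1)
                + q2 * stats.gamma.cdf(lam, s2, scale=1.0 / r2))

    # The mixture 5th percentile lies between the component 5th percentiles;
    # pad the bracket so rounding at the endpoints cannot break the sign
    # change, and expand it in the rare case padding was not enough.
    lo = 0.5 * min(stats.gamma.ppf(0.05, s1, scale=1.0 / r1),
                   stats.gamma.ppf(0.05, s2, scale=1.0 / r2))
    hi = 2.0 * max(stats.gamma.ppf(0.05, s1, scale=1.0 / r1),
                   stats.gamma.ppf(0.05, s2, scale=1.0 / r2))
    f = lambda x: cdf(x) - 0.05
    while f(lo) > 0 and lo > 1e-300:
        lo *= 0.5
    while f(hi) < 0:
        hi *= 2.0
    ebgm05 = optimize.brentq(f, lo, hi, xtol=1e-9, rtol=1e-12)
    return ebgm, ebgm05


def ebgm_arrays(a, e, params: MgpsHyperParameters
                ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EBGM and EBGM05 over arrays of observed/expected counts.

    EBGM05 is found by bisection of the posterior-mixture CDF, vectorized
    over cells; 60 halvings of the bracketing interval put the result far
    inside 1e-6 absolute tolerance on the λ scale.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    l1 = math.log(params.w) + _nb_logpmf(a, params.alpha1, params.beta1, e)
    l2 = math.log1p(-params.w) + _nb_logpmf(a, params.alpha2, params.beta2, e)
    m = np.maximum(l1, l2)
    q1 = np.exp(l1 - m)
    q2 = np.exp(l2 - m)
    tot = q1 + q2
    q1, q2 = q1 / tot, q2 / tot
    s1, r1 = params.alpha1 + a, params.beta1 + e
    s2, r2 = params.alpha2 + a, params.beta2 + e
    ebgm = np.exp(q1 * (special.digamma(s1) - np.log(r1))
                  + q2 * (special.digamma(s2) - np.log(r2)))

    p1 = stats.gamma.ppf(0.05, s1, scale=1.0 / r1)
    p2 = stats.gamma.ppf(0.05, s2, scale=1.0 / r2)
    lo, hi = 0.5 * np.minimum(p1, p2), 2.0 * np.maximum(p1, p2)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        cdf = (q1 * stats.gamma.cdf(mid, s1, scale=1.0 / r1)
               + q2 * stats.gamma.cdf(mid, s2, scale=1.0 / r2))
        below = cdf < 0.05
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return ebgm, 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Assembly and classification
# ---------------------------------------------------------------------------

def compute_statistics(t: ContingencyTable, params: MgpsHyperParameters,
                       yates: bool = True,
                       continuity: bool = False) -> SignalStatistics:
    """All four statistics for one table under one fitted MGPS prior."""
    ror, ror_lo, ror_hi = compute_ror(t, continuity)
    prr, prr_lo, prr_hi = compute_prr(t, continuity)
    chi2 = compute_chi2(t, yates=yates)
    ic, ic025 = compute_bcpnn(t)
    ebgm, ebgm05 = compute_ebgm(t, params)
    return SignalStatistics(a=t.a, expected=t.expected,
                            ror=ror, ror_lo=ror_lo, ror_hi=ror_hi,
                            prr=prr, prr_lo=prr_lo, prr_hi=prr_hi,
                            chi2=chi2, ic=ic, ic025=ic025,
                            ebgm=ebgm, ebgm05=ebgm05)


def classify_signal(s: SignalStatistics,
                    criteria: SignalCriteria = SignalCriteria()
                    ) -> SignalClassification:
    """Apply the positivity rule to one row of statistics.

    Threshold semantics follow the conventional rule: ROR and PRR compare
    with ≥, while EBGM05 and IC025 must strictly exceed their thresholds.
    Rows with NaN in any required statistic are negative with reason
    "not evaluable".
    """
    checks: list[tuple[str, float, float, bool]] = []  # name, value, thr, strict
    if criteria.a_min is not None:
        checks.append(("a", float(s.a), float(criteria.a_min), False))
    if criteria.ror_min is not None:
        checks.append(("ror", s.ror, criteria.ror_min, False))
    if criteria.prr_min is not None:
        checks.append(("prr", s.prr, criteria.prr_min, False))
    if criteria.ebgm05_min is not None:
        checks.append(("ebgm05", s.ebgm05, criteria.ebgm05_min, True))
    if criteria.ic025_min is not None:
        checks.append(("ic025", s.ic025, criteria.ic025_min, True))

    failed: list[str] = []
    passed_any = False
    for name, value, thr, strict in checks:
        if math.isnan(value):
            return SignalClassification(False, ("not evaluable",))
        ok = value > thr if strict else value >= thr
        if ok:
            passed_any = True
        else:
            failed.append(name)
    if criteria.require_all:
        positive = not failed
    else:
        positive = passed_any
    return SignalClassification(positive, tuple(sorted(failed)))


def statistics_frame(tables: dict, params: MgpsHyperParameters,
                     criteria: SignalCriteria = SignalCriteria(),
                     yates: bool = True, continuity: bool = False):
    """Statistics + classification for a set of labelled tables.

    Returns a pandas DataFrame with one row per label, mirroring the usual
    published layout: label, a, E, ROR (lo, hi), PRR (lo, hi), chi2,
    IC (IC025), EBGM (EBGM05), signal flag.  EBGM columns are computed
    vectorized; the frequentist columns use the scalar routines directly.
    """
    import pandas as pd

    labels = list(tables)
    tabs = [tables[k] for k in labels]
    a = np.array([t.a for t in tabs], dtype=float)
    e = np.array([t.expected for t in tabs], dtype=float)
    ebgm, ebgm05 = ebgm_arrays(a, e, params)

    rows = []
    for i, (lab, t) in enumerate(zip(labels, tabs)):
        ror, ror_lo, ror_hi = compute_ror(t, continuity)
        prr, prr_lo, prr_hi = compute_prr(t, continuity)
        ic, ic025 = compute_bcpnn(t)
        s = SignalStatistics(a=t.a, expected=t.expected,
                             ror=ror, ror_lo=ror_lo, ror_hi=ror_hi,
                             prr=prr, prr_lo=prr_lo, prr_hi=prr_hi,
                             chi2=compute_chi2(t, yates=yates),
                             ic=ic, ic025=ic025,
                             ebgm=float(ebgm[i]), ebgm05=float(ebgm05[i]))
        cls = classify_signal(s, criteria)
        rows.append({"label": lab if not isinstance(lab, tuple) else "/".join(lab),
                     "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                     "expected": s.expected,
                     "ror": s.ror, "ror_lo": s.ror_lo, "ror_hi": s.ror_hi,
                     "prr": s.prr, "prr_lo": s.prr_lo, "prr_hi": s.prr_hi,
                     "chi2": s.chi2, "ic": s.ic, "ic025": s.ic025,
                     "ebgm": s.ebgm, "ebgm05": s.ebgm05,
                     "signal": cls.label,
                     "reasons": ";".join(cls.reasons)})
    return pd.DataFrame(rows)
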