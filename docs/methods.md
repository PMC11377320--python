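# Methods

This document records the exact statistical definitions, the synthetic
data model, and the numerical choices the implementation makes.

## 1. Data model and counting rules

A **case** is one deduplicated safety report: demographics, a list of
drug mentions (raw name, normalized name, role code PS/SS/C/I, route,
therapy start date, indication) and a list of adverse-event terms (PTs).
Report versions share a `case_id`; deduplication keeps, per case, the
version with the latest receipt date, ties broken by the largest report
id. Whole reports are kept or dropped — fields from different versions
are never merged.

The **target cohort** contains every case with at least one
primary-suspect (PS) drug mention that normalizes to the target
substance; all other cases form the background. Drug-name normalization
uppercases, strips punctuation, collapses whitespace and then applies a
caller-supplied synonym table (brand → substance).

The default counting unit is the **event**: a distinct (case, PT) pair.
Each case contributes each of its distinct PTs once, so the margins
`a + b` (all target-cohort pairs) and `c + d` are the same for every PT
— the classical disproportionality setup. `counting_unit: case` counts
distinct cases instead. SOC-level tables aggregate PT counts through a
PT→SOC map (conserving totals); `soc_within_case_dedup: true` instead
counts a case once per SOC even when several of its PTs map there.

Age harmonization: decades ×10, years ×1, months ÷12, weeks ÷52.14,
days ÷365.25; hour-coded and >120-year ages become missing. FAERS dates
are 8-, 6- or 4-digit; partial dates resolve to the first day of the
period, malformed dates degrade to missing with a logged count.

## 2. Disproportionality statistics

With the 2×2 table (a, b, c, d), N = a+b+c+d and E = (a+c)(a+b)/N:

**ROR** = ad/bc, with 95 % CI
`exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`.

**PRR** = [a/(a+b)] / [c/(c+d)], with 95 % CI
`exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`.

Both are undefined (reported as NaN, classified "not evaluable") when a
zero cell makes them so; an optional Haldane–Anscombe +0.5 continuity
correction is available.

**Pearson χ²** uses the Yates continuity correction by default
(`(|ad − bc| − N/2)²·N / [(a+b)(c+d)(a+c)(b+d)]`, with the correction
floored at zero), switchable to the uncorrected statistic.

**BCPNN information component** (closed form, Bate et al. 1998): with
cₓ = a+b, c_y = a+c, c_xy = a and hyper-priors α₁ = β₁ = 1, α = β = 2,
γ₁₁ = 1, γ = γ₁₁(N+α)(N+β)/((cₓ+α₁)(c_y+β₁)):

```
IC   = log2[ (c_xy + γ11)(N + α)(N + β) / ((N + γ)(cx + α1)(cy + β1)) ]
V(IC)= [ (N − c_xy + γ − γ11) / ((c_xy + γ11)(1 + N + γ))
       + (N − cx + α − α1) / ((cx + α1)(1 + N + α))
       + (N − cy + β − β1) / ((cy + β1)(1 + N + β)) ] / ln²2
IC025 = IC − 2·√V(IC)
```

**MGPS / EBGM** (DuMouchel 1999): counts are modeled as
a ~ Poisson(λE) with λ drawn from a two-component gamma mixture prior
`w·Γ(α₁, β₁) + (1−w)·Γ(α₂, β₂)` (rate parameterization). The marginal
likelihood of each cell is the matching mixture of negative binomials;
the five hyper-parameters are fitted by maximum likelihood over **all**
(PS drug, event) cells of the database, not just the target drug's. The
posterior for a cell is again a two-gamma mixture with components
Γ(αᵢ+a, βᵢ+E) and weights proportional to the component marginal
likelihoods. Then

- `EBGM = exp(Σᵢ Qᵢ·(ψ(αᵢ+a) − ln(βᵢ+E)))` — the posterior geometric
  mean, using the digamma identity `E[ln λ] = ψ(shape) − ln(rate)`;
- `EBGM05` — the posterior 5th percentile, found by root-finding on the
  mixture CDF.

**Positivity rule**: a term is a signal when all of `a ≥ 3`, `ROR ≥ 3`,
`PRR ≥ 2`, `EBGM05 > 2` (strict) and `IC025 > 0` (strict) hold. Each
threshold is configurable or disableable; a NaN in any required
statistic yields "not evaluable" and a negative call.

## 3. Numerical choices

- MGPS optimization works on transformed parameters
  (log α₁, log β₁, log α₂, log β₂, logit w) with box bounds ±10. On
  near-null data the likelihood has a flat ridge toward a degenerate
  point-mass prior (α, β → ∞ at fixed ratio), so the fit runs L-BFGS-B
  first, then up to three rounds of bounded Nelder–Mead polish plus an
  L-BFGS-B restart; convergence is declared when any stage succeeds or
  the final improvement is ≤ 1e-8. Parameters on the ridge are not
  individually identifiable, but the implied shrinkage (the EBGM values)
  is stable — tests assert invariance at that level.
- Mixture log-likelihoods combine component log-densities with
  `log_expit`-based weights to avoid overflow.
- The scalar EBGM05 uses Brent's method on a bracket padded to
  `[0.5·min, 2·max]` of the component 5th percentiles (the mixture
  quantile provably lies between the unpadded endpoints; padding guards
  against sign loss from rounding when one posterior weight is ≈ 0).
  The vectorized path uses 60 bisection steps of the same bracket.
- Published-style percentages use decimal half-up rounding to two
  decimals (`Decimal.quantize(…, ROUND_HALF_UP)`), not binary
  banker's rounding.
- All report files are written with fixed float formatting (`%.6f`),
  fixed sort orders and `\n` line endings, so identical config +
  identical inputs ⇒ byte-identical outputs.

## 4. Synthetic data generator

Each synthetic case gets demographics, a receipt date inside the
configured year range, one PS drug (uniform over the drug list) and
optional concomitants. Events are drawn in two stages:

1. **Per-PT Bernoulli**: each PT occurs with probability
   `min(1, λ(drug, PT) · background_rate)`, where λ = 1 except for
   planted (drug, PT, λ) signals.
2. **Drug-blind top-up**: the case's PT list is topped up with uniform
   draws to `1 + Poisson(1)` distinct PTs, ignoring the drug.

The top-up guarantees every case has at least one event without
breaking the null (it is independent of drug), but it **dilutes** the
realized disproportionality: at low background rates most events come
from the top-up and the realized ROR of a planted pair sits well below
λ. At `background_rate = 0.05` the Bernoulli component dominates and
the realized ratio approaches λ — the replicate-study configurations
below are chosen in that regime.

Duplicates are modeled by re-emitting a fraction of cases as an earlier
version (lower report id, receipt date 30 days earlier, and for the
hand-written fixture a deliberately different event list so that wrong
deduplication is detectable). Missing ages and missing therapy dates
are injected at configurable rates. Generation is a pure function of
the config (including seed): writing the same config twice is
byte-identical.

A hand-written 20-row fixture (`fixture_small`) with fully enumerated
expected values (18 cases after dedup, target cohort cases 1–8, the
planted PT's 2×2 table a=6, b=8, c=1, d=14) anchors the ingest and
cohort tests.

## 5. Validation studies

The acceptance suite runs, per seed:

- **Oracle equivalence** — ROR/PRR and their CIs against
  `statsmodels.stats.Table2x2`, χ² against `scipy.stats.chi2_contingency`
  (both Yates variants) on 500–1000 random tables (observed worst
  relative error ≤ 1e-12); EBGM/EBGM05 against adaptive-quadrature /
  high-precision root-finding oracles on random posteriors (≤ 1e-6).
- **Prior recovery** — 5 000 cells simulated from λ ~ Γ(2, 4): the
  dominant fitted component recovers (α, β) within 25 % with weight
  ≥ 0.9.
- **Power** — 200 replicates of 4 000 cases, 8 drugs, 30 PTs,
  background rate 0.05, one planted λ = 10 pair: sensitivity ≥ 95 %
  (observed 100 %). These sizes are this package's own design choice to
  make the study decisive yet fast; the realized per-replicate signal is
  a ≈ 260 events at ROR ≈ 7.
- **Specificity** — 200 all-null replicates of 2 000 cases, 8 drugs,
  25 PTs: fraction of flagged (drug, PT) pairs < 1 % (observed 0 %).
- **Determinism** — two pipeline runs on the fixture compare
  byte-identical; deduplication is idempotent.

## 6. Limitations

- Spontaneous-report disproportionality measures reporting association,
  not incidence or causality; all the usual FAERS caveats (reporting
  bias, no denominator, duplicate residue) apply to real data.
- Linking assumes the quarterly convention that THER/INDI rows attach
  positionally to DRUG rows of the same report; cross-quarter version
  chains are handled only through case-id deduplication.
- The MGPS prior is fitted per counting level (PT or SOC) over PS-drug
  cells only; concomitant-only exposures are not modeled.
- The generator's event model is deliberately simple (no within-case PT
  correlation beyond the top-up, no secular trends in signal strength).
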