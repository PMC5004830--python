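# Methods

`laycurve` implements a complete analysis chain for poultry egg-production
studies: parametric laying-curve estimation from hen-week records, model
evaluation, nested-model comparison of groups, Z-linked haplotype analysis
for hemizygous hens, and relative qPCR quantification. This note records the
models, the estimation and testing procedures, the numerical choices, and
what the synthetic-data generators do and do not emulate.

## Laying-curve models

The observed response is the weekly laying rate of hen *i* at age *t*
(weeks), `y_it = eggs_it / 7 ∈ [0, 1]`. Three mean-curve families are
provided; all describe the same rise–plateau–decline shape.

**Segmented polynomial.** A cubic rise from lay onset to the peak, then a
linear decline:

    y(t) = p − 3p((tp−t)/tip)² + 2p((tp−t)/tip)³   for tp−tip ≤ t ≤ tp
    y(t) = p − s(t−tp)                             for t > tp

with `p` the peak rate, `s` the weekly post-peak decline (rate/week), `tp`
the age at peak (weeks) and `tip` the onset-to-peak interval (weeks, > 0).
The curve is continuous at `tp` (both branches equal `p`). The original
formulation leaves `t < tp − tip` undefined; we define it as exactly 0
(pre-lay) and clamp the linear branch at 0, so the curve is never negative.

**Yang.** A logistic maturation front times an exponential decline:

    y(t) = a·e^(−x·t) / (1 + e^(−c·(t−d)))

with scale `a ≥ 0`, maturity-variation reciprocal `c > 0` (1/weeks),
post-peak decline `x` (1/weeks) and mean age at sexual maturity `d` (weeks).
At `t = d` the curve passes through `a·e^(−x·d)/2`.

**Persistency.** A smoothed trapezoid built from ramps
`S(t,k) = 0.3·[ln(e^(t/0.3) + e^(k/0.3)) − ln(1 + e^(k/0.3))] ≈ max(t−k, 0)`:

    y(t) = (yp/(t2−t1))·[S(t,t1) − S(t,t2)] + b4·S(t, t2+P)

rising between `t1` and `t2` to the plateau `yp`, constant for `P` weeks
("persistency"), then declining at `b4` per week. The smoothing constant 0.3
weeks is structural, never fitted; the ramp approximation error is at most
`0.3·ln 2 ≈ 0.208` weeks, attained at `t = k`. All ramp evaluations use
log-sum-exp: `e^(t/0.3)` reaches ~1e72 at t = 50, so the naive form
overflows.

## Least-squares estimation

Parameters minimise `Σ (y_it − y(t))²` over hen-week records (individual
records, not weekly means; a weekly-means fit is equivalent up to a
row-weighting and can be emulated by passing one pseudo-hen of mean rates).
Because predictions depend on week only, the implementation reduces the
records to per-(group, week) sufficient statistics `(n_t, Σy, Σy²)` and
evaluates SSE, gradients and normal equations exactly on those — identical
results, orders-of-magnitude faster Monte-Carlo studies.

The optimiser is Gauss-Newton with step halving: solve the normal equations
for the step, halve it until SSE does not increase, project each trial onto
the feasible box (`tip > 0`, `c > 0`, `t2 > t1`, `P ≥ 0`, nonnegative
peaks), and stop when the relative SSE decrease falls below 1e−5 (the
classical NLIN default; configurable) or after 200 iterations. Accepted
iterations never increase SSE. Starting values are data-driven: peak = max
weekly mean rate, timing parameters from the argmax week, lay onset = first
week above 5% of the peak, `d` from the half-peak crossing, declines from
the late-window trend. If a persistency fit ends with `t2 + P` beyond the
last observed week — a region where the gradient with respect to `P`
vanishes and the plateau end is unidentifiable — the fit restarts once with
the plateau end pulled back inside the window and keeps the better SSE.

Standard errors come from the residual-variance-scaled inverse Gauss-Newton
normal matrix; 95% confidence intervals use the t quantile at the residual
degrees of freedom `n_records − p` (not 1.96). An estimate that finishes on
a constraint boundary (e.g. a plateau fitted at `P = 0`) is flagged and its
SE/CI suppressed, since Wald theory is invalid on the boundary. A singular
normal matrix is reported as non-convergence with diagnostics, never as
silent output. A hidden `linear` family (`y = α + βt`) exists solely so
tests can compare the machinery against closed-form least squares.

## Goodness of fit

For a fit with SSE, `n` records and `k` parameters:

* `AIC = n·ln(SSE/n) + 2k` (−∞ sentinel when SSE = 0);
* `MSE = SSE/(n − k)`. The textbook denominator `nm − p` assumes a complete
  hen × week grid; real grids are incomplete, so the actual record count is
  used;
* `R² = 1 − SSE/SS_total` with SS_total centered about the grand mean rate —
  the convention that makes a grand-mean predictor score 0. An uncentered
  variant is available behind a flag.
* `MME = (1/m)·Σ_t (ŷ̄_t − ȳ_t)/ȳ_t`, the mean over recording weeks of the
  relative deviation of the predicted from the observed weekly mean rate.
  Positive MME means overall overestimation. Weeks with `ȳ_t = 0` (pre-lay
  weeks can have no eggs at all) are excluded because the ratio is undefined
  there, and the number of weeks used is reported. MME is sensitive to
  near-zero early weeks, where small absolute deviations are huge relative
  ones; this is a property of the statistic, not a defect of the fit.

## Group comparison

The **sum-of-squares reduction test** compares a reduced model (one
parameter set for the pooled records) against a full model (one set per
group):

    F_R = [(SSE_r − SSE_f)/(df_r − df_f)] / (SSE_f/df_f)

referred to the F distribution on `(df_r − df_f, df_f)` degrees of freedom.
The full model is estimated as a single joint problem with the non-reference
groups parameterised as `reference + Δpar`, initialised from the reduced
estimates — so `SSE_f ≤ SSE_r` holds structurally and the joint covariance
directly provides Δpar standard errors. A Δpar is significant when its 95%
CI (t quantile at the full-model residual df; the multiplier is not stated
in the classical sources, t is the SAS-style convention) excludes zero.
Multi-group comparisons run all contrasts against one reference inside one
joint fit; no multiple-testing correction is applied. P-values below 1e−6
are printed as "< 0.000001".

Caveat: weekly binomial rates are heteroscedastic (variance `r(1−r)/7`),
while the F test assumes homoscedastic errors. With gently-shaped curves the
test is close to nominal (the calibration suite measures size ≈ 0.05–0.06 at
the low-producing-flock truth); steeper logistic transitions combined with
binomial noise can inflate it, which is inherent to applying unweighted
least squares to rate data. Weighted or quasi-binomial alternatives are out
of scope because the reference procedure is unweighted.

## Haplotype analysis

Hens are ZW: each female carries a single Z chromosome, so her haplotype
over the 8 VLDLR tag-SNP sites is read directly off the hemizygous genotype
calls — no EM phasing. Males (ZZ) are excluded with a logged note; a
heterozygous call in a female is a data error, and samples with missing
calls are dropped with a count.

For association testing, haplotypes are collapsed into groups: explicit
merge sets are united first (sub-threshold members of a merge are retained),
then remaining haplotypes below the frequency threshold (default 5%) are
discarded. Group hen counts are `round(Σ member frequency × N)`. Merged
groups are labelled with slash notation at the differing sites, e.g.
`ATAATA(A/C)T`.

"Highly similar" is not a self-defining rule, so merges are explicit
configuration. An optional suggester implements the one deterministic rule
consistent with the published grouping: classify haplotypes as
*reference-like* (≤ 2 mismatches from a reference panel such as the fixed
haplotypes of a selected breed; candidates at any frequency) or *other*
(candidates only when at or above the frequency threshold), then merge
single-mismatch connected components **within** each class. The class
boundary matters: the association contrast is with-vs-without reference-like
haplotypes, and unrestricted single-linkage would chain across it (e.g.
ATAATACT and GTAATACT differ at one site yet belong to different groups).

The in-silico restriction digest is exact partition arithmetic: fragments
are successive differences of `[0, cuts…, length]` and always sum to the
amplicon length. For the RO-mutation screen (559 bp amplicon, Eco57I), the
wild-type allele cut at 85 gives 85 + 474 bp; an allele cut at 85 and 451
gives 85 + 366 + 108 bp. Note that a published four-band description
(85/474/108/451) for carriers is arithmetically inconsistent with a 559 bp
amplicon — 451 is the cut coordinate, not a fragment; the correct third and
fourth bands are 366 and 108 bp. The implementation reports the exact
arithmetic.

## Relative expression

The comparative-Ct method: technical replicate Cts are averaged per sample
and gene; `ΔCt = Ct_target − Ct_reference`; `ΔΔCt = ΔCt − mean ΔCt of the
calibrator group`; fold change `= 2^(−ΔΔCt)`. The calibrator group's
geometric-mean fold is exactly 1 by construction, and fold changes are
invariant to any global Ct shift. Amplification-efficiency correction and
multi-reference normalisation are out of scope.

Group tests: classical one-way ANOVA (on the fold scale, matching the usual
display; a log2-fold analysis is available to the caller since ratios are
skewed), followed by Duncan's multiple range test. For a stretch of `k`
ranked means the critical range is `q(1−α_k; k, df)·√(MS_within/n_h)` with
the protected level `α_k = 1 − (1−α)^(k−1)`, `q` the studentized range
quantile (computed from scipy's distribution, no table files) and `n_h` the
harmonic mean of the group sizes (standard practice for unbalanced groups).
Step-down blocking applies: a stretch whose extremes do not differ is
homogeneous and no pair inside it is separated; letter groups are emitted
for display. Duncan's test is liberal by design; the suite only guards that
null separations stay near the expected rate.

## Synthetic data

The generators reproduce the statistical structure the analyses assume, and
only that:

* **Egg records** — weeks 17–50 of age (34 recording weeks), true weekly
  rate = the group's curve clamped into [0, 1], `eggs ~ Binomial(7, rate)`.
  Binomial is the default because an observed rate is a 7-day count divided
  by 7. A Gaussian-on-rate mode exists to match the least-squares error
  model exactly; its "eggs" are kept continuous (`rate × 7`) so that sd = 0
  reproduces the curve without rounding. Optional uniform missingness thins
  hen-weeks.
* **Genotypes** — one categorical haplotype draw per female, spelt out as
  per-site alleles; the inverse of haplotype calling by construction.
* **qPCR plates** — reference-gene Cts at a fixed baseline, target Cts
  offset by a group ΔCt, i.i.d. normal replicate noise, in the 6 × 3
  (samples × replicates) layout.

Not emulated: the half-sib family structure of real layer flocks (records
are treated as independent, as the reference analysis also does), seasonal
or management effects on laying, overdispersion beyond binomial, linkage
between tag sites within a population (haplotypes are drawn directly, so LD
is implicit in the table), PCR efficiency differences and plate effects.
Passing tests therefore demonstrate correctness of the procedures under
their stated assumptions, not robustness to those violations.

All generators are pure functions of (configuration, seed).

## Problem sizes and tolerances in the test suite

Monte-Carlo suites use the study's own sizes where those matter: parameter
recovery draws 91-hen flocks (200 seeds; bias within 2 empirical SEs, 99% CI
coverage ≥ 95%), SSRT size uses 500 null replicates and power 200 replicates
at 100 hens/group, and haplotype round-trips use 381 females. Oracle
comparisons (linear family vs closed-form OLS) are asserted to 1e−8; exact
identities to 1e−10–1e−12; published worked values (34 weeks, 85 + 474 bp,
group counts 42/87/108/75 totalling 312, NC-haplotype shares 100%/92.5%) are
asserted exactly.

## Known limitations

* Unweighted least squares on binomial rates: see the heteroscedasticity
  caveat above.
* `P` (plateau duration) is weakly identified when the plateau end
  approaches the recording boundary; its CI is honest about this (very wide)
  and the boundary case `P = 0` suppresses Wald output entirely.
* MME explodes when early-week mean rates are near zero; `m_used` makes the
  denominator explicit.
* Duncan's test controls the comparisonwise, not familywise, error rate;
  that is its definition, not a bug.
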