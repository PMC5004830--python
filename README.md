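# laycurve

Laying-curve analysis for poultry egg-production studies: fit nonlinear
models of the weekly laying rate to hen-week records, evaluate and compare
them, test for curve differences between genetic groups, analyse Z-linked
haplotypes in hemizygous hens, and quantify relative gene expression from
qPCR plates. Written for quantitative geneticists and breeders analysing
layer-flock data; every stage can also run on built-in synthetic data, so
the whole pipeline is exercisable without any private records.

## What it computes

**Laying curves.** The weekly rate `y_it = eggs/7 ∈ [0,1]` of hen *i* at age
*t* (weeks) is modelled by one of three families:

* segmented polynomial — cubic rise to a peak `p` at age `tp`, linear
  decline `s` after it;
* Yang — `y(t) = a·e^(−x·t) / (1 + e^(−c·(t−d)))`, a logistic maturation
  front (mean maturity age `d`) times an exponential decline `x`;
* persistency — a smoothed trapezoid: rise between `t1` and `t2` to peak
  `yp`, a plateau of duration `P` ("persistency"), then a decline `b4`.

Fitting is nonlinear least squares by Gauss-Newton with step halving
(relative-SSE convergence 1e−5), with standard errors from the scaled
inverse normal matrix and t-based 95% CIs. Goodness of fit is reported as
AIC, MSE, R² and MME (signed mean relative error of weekly means).

**Group comparison.** The sum-of-squares reduction test (SSRT) compares a
pooled fit against per-group fits,
`F_R = [(SSE_r − SSE_f)/(df_r − df_f)]/(SSE_f/df_f)`, and per-parameter
contrasts Δpar (group minus reference, estimated inside one joint
reparameterized fit) are significant when their 95% CI excludes zero.

**Haplotypes.** Hens are ZW, so a female's haplotype over the 8 VLDLR
tag-SNP sites on chromosome Z is read directly off her hemizygous genotype.
The package builds frequency tables, groups haplotypes for association
testing (≥ 5% frequency, highly similar haplotypes merged), and computes
exact in-silico PCR-RFLP digests (e.g. the Eco57I screen for the
laying-null RO mutation).

**Expression.** 2^−ΔΔCt fold changes against a calibrator group, one-way
ANOVA and Duncan's multiple range test (studentized-range critical values at
protected levels, no lookup tables).

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
from laycurve import SimulationConfig, fit_model, gof_report, simulate_egg_records
from laycurve.datasets import CURVE_ESTIMATES

truth = CURVE_ESTIMATES["NC"]["yang"]        # a=0.96, c=1.00, x=0.003, d=19.9
config = SimulationConfig(family="yang", group_params={"NC": truth},
                          n_hens={"NC": 91}, seed=2024)
records = simulate_egg_records(config)       # 91 hens x weeks 17-50, Binomial(7, rate)
fit = fit_model(records, "yang")
print(fit.summary())
print(gof_report(fit, records))
```

prints

```
    estimate        se   ci95_low  ci95_high  boundary
a   0.951819  0.014833   0.922735   0.980903     False
c   0.946447  0.035198   0.877433   1.015462     False
x   0.002746  0.000414   0.001933   0.003558     False
d  19.906004  0.045958  19.815893  19.996116     False
GofReport(aic=-12357.288970180027, mse=0.01840294693918589, r2=0.7063119750504346, mme=0.0008499506985869751, m_used=34)
```

The fit recovers the generating parameters within their standard errors from
3,094 noisy hen-week records: peak-scale `a` ≈ 0.95 (truth 0.96), maturity
age `d` ≈ 19.9 weeks, and a slow post-peak decline `x` ≈ 0.003 per week. MME
near zero says the fitted curve neither over- nor under-estimates the weekly
mean rates overall; R² ≈ 0.71 reflects irreducible binomial noise in
individual hen-weeks, not lack of fit.

The `examples/` directory has one narrative script per capability
(`fit_laying_curves.py`, `compare_groups.py`, `haplotype_analysis.py`,
`qpcr_expression.py`), and the same stages are available from the shell:

```bash
laycurve simulate --family yang --group LY=381 --group NC=91 --seed 1 --out records.csv
laycurve fit records.csv --family yang --group NC
laycurve compare records.csv --family yang --reference NC
laycurve digest --length 559 --cut 85        # 85 bp + 474 bp = 559 bp
```

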