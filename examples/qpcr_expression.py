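"""Relative VLDLR expression by 2^-ΔΔCt with ANOVA and Duncan's range test.

Simulates the study's qPCR design (three groups, 6 samples each, 3
technical replicates; GAPDH reference) with no true group effect, computes
fold changes relative to the calibrator group, and tests for differences.
Expect fold changes near 1 in every group and a non-significant ANOVA —
the published finding was that expression did not differ between haplotype
groups.
"""

from laycurve import anova_oneway, duncan_mrt, fold_change_ddct, simulate_qpcr
from laycurve.group_compare import format_p_value

plate = simulate_qpcr(
    {"LY_without_hap": 5.0, "LY_with_hap": 5.0, "NC": 5.0},
    replicate_sd=0.25, n_samples=6, n_replicates=3, seed=34, tissue="ovary",
)
result = fold_change_ddct(plate, calibrator_group="LY_without_hap",
                          tissue="ovary")
print("group fold-change summary (mean ± SD relative to the calibrator):")
print(result.per_group.to_string(index=False))

anova = anova_oneway(result.per_sample["fold"], result.per_sample["group"])
print(f"\nANOVA: F({anova.df_between}, {anova.df_within}) = {anova.f:.3f}, "
      f"p {format_p_value(anova.p_value)}")

sizes = result.per_sample.groupby("group").size()
means = result.per_sample.groupby("group")["fold"].mean()
mrt = duncan_mrt(means, sizes, anova.ms_within, anova.df_within, alpha=0.05)
print("Duncan's multiple range test letters (shared letter = no difference):")
for group in mrt.order:
    print(f"  {group:>16s}  mean fold {means[group]:.3f}  [{mrt.letters[group]}]")
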