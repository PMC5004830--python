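"""Compare laying curves between two groups with the SSRT and Δpar contrasts.

Simulates a low-producing indigenous-type flock and a second group whose
Yang scale parameter a is 0.12 lower (a peak-rate difference of the size
reported between haplotype groups in field data), then asks: do the two
groups need separate curve parameters?

The sum-of-squares reduction test (SSRT) compares a pooled fit against a
joint per-group fit; Δpar gives per-parameter contrasts with 95% CIs, a CI
excluding 0 marking the parameter that differs.
"""

from laycurve import SimulationConfig, delta_par, simulate_egg_records, ssrt_test
from laycurve.datasets import CURVE_ESTIMATES

base = dict(CURVE_ESTIMATES["LY"]["yang"])
lowered = dict(base)
lowered["a"] = base["a"] - 0.12

config = SimulationConfig(
    family="yang",
    group_params={"with_hap": base, "without_hap": lowered},
    n_hens={"with_hap": 100, "without_hap": 100},
    seed=7,
)
records = simulate_egg_records(config)

result = ssrt_test(records, "yang")
print(f"SSRT: F = {result.f_r:.3f} on "
      f"({result.df_reduced - result.df_full}, {result.df_full}) df, "
      f"p {result.p_display}")
print(f"SSE pooled {result.sse_reduced:.2f} -> per-group {result.sse_full:.2f}\n")

contrasts = delta_par(records, "yang", reference_group="with_hap")
print(contrasts.table().to_string(index=False))
print("\nOnly the scale contrast (Δa ≈ -0.12) should be significant: the")
print("groups share maturity timing (c, d) and post-peak decline (x).")
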