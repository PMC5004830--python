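"""2^-ΔΔCt quantification, one-way ANOVA and Duncan's multiple range test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laycurve import anova_oneway, duncan_mrt, fold_change_ddct, simulate_qpcr


def _plate(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "tissue", "gene",
                                       "replicate", "ct"])


def _simple_plate(dcts, calibrator_dct=5.0, tissue="ovary"):
    """One sample per entry; reference gene fixed at Ct 18."""
    rows = []
    for i, (group, dct) in enumerate(dcts):
        s = f"s{i}"
        rows.append([s, group, tissue, "GAPDH", 1, 18.0])
        rows.append([s, group, tissue, "VLDLR", 1, 18.0 + dct])
    return _plate(rows)


class TestFoldChange:
    def test_sample_at_calibrator_mean_has_unit_fold(self):
        plate = _simple_plate([("cal", 5.0), ("cal", 5.0), ("case", 5.0)])
        res = fold_change_ddct(plate, "cal", "ovary")
        case = res.per_sample[res.per_sample["group"] == "case"]
        assert case["fold"].iloc[0] == pytest.approx(1.0)

    def test_one_cycle_advantage_doubles(self):
        plate = _simple_plate([("cal", 5.0), ("cal", 5.0), ("case", 4.0)])
        res = fold_change_ddct(plate, "cal", "ovary")
        case = res.per_sample[res.per_sample["group"] == "case"]
        assert case["fold"].iloc[0] == pytest.approx(2.0)

    def test_forced_arithmetic(self):
        # Ct_target 24, Ct_ref 18, calibrator mean dct 5 -> fold 0.5
        plate = _plate([
            ["c0", "cal", "ovary", "GAPDH", 1, 18.0],
            ["c0", "cal", "ovary", "VLDLR", 1, 23.0],
            ["x0", "case", "ovary", "GAPDH", 1, 18.0],
            ["x0", "case", "ovary", "VLDLR", 1, 24.0],
        ])
        res = fold_change_ddct(plate, "cal", "ovary")
        case = res.per_sample.set_index("sample").loc["x0"]
        assert case["dct"] == pytest.approx(6.0)
        assert case["ddct"] == pytest.approx(1.0)
        assert case["fold"] == pytest.approx(0.5)

    def test_calibrator_geometric_mean_fold_is_one(self):
        plate = simulate_qpcr({"cal": 5.0, "case": 4.2}, replicate_sd=0.3, seed=8)
        res = fold_change_ddct(plate, "cal", "ovary")
        cal = res.per_sample[res.per_sample["group"] == "cal"]["fold"]
        assert np.exp(np.mean(np.log(cal))) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_global_ct_shift(self):
        plate = simulate_qpcr({"cal": 5.0, "case": 4.0}, replicate_sd=0.2, seed=3)
        res1 = fold_change_ddct(plate, "cal", "ovary")
        shifted = plate.assign(ct=plate["ct"] + 2.5)
        res2 = fold_change_ddct(shifted, "cal", "ovary")
        assert res1.per_sample["fold"].to_numpy() == pytest.approx(
            res2.per_sample["fold"].to_numpy(), abs=1e-12
        )

    def test_sample_missing_reference_excluded_with_warning(self):
        plate = _simple_plate([("cal", 5.0), ("cal", 5.0), ("case", 4.0)])
        plate = plate.drop(plate[(plate["sample"] == "s2")
                                 & (plate["gene"] == "GAPDH")].index)
        with pytest.warns(UserWarning, match="excluding 1"):
            res = fold_change_ddct(plate, "cal", "ovary")
        assert "s2" not in set(res.per_sample["sample"])

    def test_absent_calibrator_raises(self):
        plate = _simple_plate([("case", 4.0), ("case", 5.0)])
        with pytest.raises(ValueError, match="calibrator"):
            fold_change_ddct(plate, "cal", "ovary")


class TestAnova:
    def test_textbook_two_group_f(self):
        values = [1, 2, 3, 2, 3, 4]
        labels = ["a"] * 3 + ["b"] * 3
        res = anova_oneway(values, labels)
        assert res.f == pytest.approx(1.5, abs=1e-9)
        ref = stats.f_oneway([1, 2, 3], [2, 3, 4])
        assert res.f == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_equal_observations_give_null(self):
        res = anova_oneway([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.f == 0.0
        assert res.p_value == 1.0

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=12)
        labels = np.array(["a", "b", "c"] * 4)
        res1 = anova_oneway(values, labels)
        perm = rng.permutation(12)
        res2 = anova_oneway(values[perm], labels[perm])
        assert res1.f == pytest.approx(res2.f, abs=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_oneway([1, 2, 3], ["a", "a", "b"])


class TestDuncan:
    def test_identical_means_share_a_letter(self):
        res = duncan_mrt({"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 6, "b": 6, "c": 6},
                         residual_ms=0.5, df=15)
        assert not res.any_separation()
        assert len({res.letters[g] for g in ("a", "b", "c")}) == 1

    def test_two_groups_match_studentized_range_test(self):
        """With k=2 Duncan reduces to the plain studentized-range decision."""
        ms, df, n = 0.8, 10, 6
        q_crit = stats.studentized_range.ppf(0.95, 2, df)
        crit = q_crit * np.sqrt(ms / n)
        for gap, expect in ((crit * 1.05, True), (crit * 0.95, False)):
            res = duncan_mrt({"hi": gap, "lo": 0.0}, {"hi": n, "lo": n}, ms, df,
                             alpha=0.05)
            assert res.any_separation() is expect

    def test_critical_ranges_nondecreasing_in_span(self):
        res = duncan_mrt({g: float(i) for i, g in enumerate("abcde")},
                         {g: 6 for g in "abcde"}, residual_ms=1.0, df=25)
        ranges = [res.critical_ranges[k] for k in sorted(res.critical_ranges)]
        assert all(b >= a for a, b in zip(ranges, ranges[1:]))

    def test_clear_separation_gets_distinct_letters(self):
        res = duncan_mrt({"low": 0.0, "high": 50.0}, {"low": 6, "high": 6},
                         residual_ms=1.0, df=10)
        assert res.any_separation()
        assert res.letters["low"] != res.letters["high"]

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            duncan_mrt({"a": 1.0, "b": 2.0}, {"a": 3, "b": 3}, 1.0, df=0)


def test_null_plates_rarely_separate():
    """Regression guard: no group effect => Duncan separates in <= ~10% of runs."""
    n_sep = 0
    N = 120
    for seed in range(N):
        plate = simulate_qpcr({"g1": 5.0, "g2": 5.0, "g3": 5.0},
                              replicate_sd=0.2, n_samples=6, seed=seed)
        res = fold_change_ddct(plate, "g1", "ovary")
        anova = anova_oneway(res.per_sample["fold"], res.per_sample["group"])
        sizes = res.per_sample.groupby("group").size()
        means = res.per_sample.groupby("group")["fold"].mean()
        mrt = duncan_mrt(means, sizes, anova.ms_within, anova.df_within)
        n_sep += mrt.any_separation()
    assert n_sep / N <= 0.15  # liberal test; guard with slack for MC error
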