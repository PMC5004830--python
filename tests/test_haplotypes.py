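"""Haplotype calling, frequencies, similarity, grouping, restriction digest."""

import numpy as np
import pandas as pd
import pytest

from laycurve import (
    HaplotypeGroupingSpec,
    call_hemizygous_haplotypes,
    group_haplotypes,
    hamming_similarity,
    haplotype_frequencies,
    restriction_fragments,
    simulate_genotypes,
    suggest_merges,
)
from laycurve.datasets import (
    LOHB_HAPLOTYPE_FREQS,
    LY_HAPLOTYPE_FREQS,
    NC_HAPLOTYPE_FREQS,
    RO_AMPLICON_LENGTH,
    RO_MUTANT_CUTS,
    RO_WILDTYPE_CUTS,
    SITE_ORDER,
)
from laycurve.haplotypes import GenotypeDataError, frequency_table, merged_label


class TestCalling:
    def test_alleles_concatenate_in_site_order(self):
        row = dict(zip(SITE_ORDER, "ATAATAAT"))
        row["sex"] = "F"
        genotypes = pd.DataFrame([row], index=["hen1"])
        haps = call_hemizygous_haplotypes(genotypes)
        assert haps["hen1"] == "ATAATAAT"

    def test_heterozygous_female_is_data_error(self):
        row = dict(zip(SITE_ORDER, "ATAATAAT"))
        row[SITE_ORDER[2]] = "A/G"
        row["sex"] = "F"
        genotypes = pd.DataFrame([row], index=["hen1"])
        with pytest.raises(GenotypeDataError, match="hen1"):
            call_hemizygous_haplotypes(genotypes)

    def test_males_excluded_and_empty_warns(self):
        row = dict(zip(SITE_ORDER, "GGGGCGCC"))
        row["sex"] = "M"
        genotypes = pd.DataFrame([row], index=["rooster1"])
        with pytest.warns(UserWarning):
            haps = call_hemizygous_haplotypes(genotypes)
        assert len(haps) == 0

    def test_missing_call_drops_sample_with_count(self):
        ok = dict(zip(SITE_ORDER, "GGGGCGCC"), sex="F")
        bad = dict(zip(SITE_ORDER, "GGGGCGCC"), sex="F")
        bad[SITE_ORDER[0]] = None
        genotypes = pd.DataFrame([ok, bad], index=["a", "b"])
        with pytest.warns(UserWarning, match="dropped 1"):
            haps = call_hemizygous_haplotypes(genotypes)
        assert list(haps.index) == ["a"]


class TestFrequencies:
    def test_published_nc_distribution(self):
        haps = ["ATAATAAC"] * 66 + ["ATAACAAC"] * 34
        table = haplotype_frequencies(haps, "NC")
        assert table["frequency"].tolist() == pytest.approx([0.66, 0.34])
        assert table["count"].tolist() == [66, 34]

    def test_single_haplotype(self):
        table = haplotype_frequencies(["GGGGCGCC"], "x")
        assert table["frequency"].tolist() == [1.0]

    @pytest.mark.parametrize("freqs", [LY_HAPLOTYPE_FREQS, NC_HAPLOTYPE_FREQS,
                                       LOHB_HAPLOTYPE_FREQS])
    def test_frequencies_normalise(self, freqs):
        rng = np.random.default_rng(0)
        haps = rng.choice(list(freqs), size=200, p=np.array(list(freqs.values())) /
                          sum(freqs.values()))
        table = haplotype_frequencies(haps)
        assert table["frequency"].sum() == pytest.approx(1.0, abs=1e-9)


class TestSimilarity:
    @pytest.mark.parametrize(
        "h1, h2, matches",
        [
            ("ATAATAAT", "ATAATAAC", 7),
            ("ATAATAAT", "ATAATAAT", 8),
            ("ATAATACT", "ATAATAAC", 6),  # the NC-like pairing: 2 mismatches
            ("ATAATACT", "ATAACAAC", 5),
        ],
    )
    def test_positionwise_matches(self, h1, h2, matches):
        m, L = hamming_similarity(h1, h2)
        assert (m, L) == (matches, 8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_similarity("ATA", "ATAT")


class TestGrouping:
    def test_published_four_group_partition(self):
        """Explicit merges reproduce the published hen counts 42/87/108/75."""
        table = frequency_table(LY_HAPLOTYPE_FREQS, "LY", n=381)
        spec = HaplotypeGroupingSpec(
            min_frequency=0.05,
            merge_sets=(("ATAATAAT", "ATAATACT"), ("GTAGTACT", "GTAATACT")),
        )
        groups = group_haplotypes(table, spec, population_size=381)
        by_label = {g.label: g for g in groups}
        assert set(by_label) == {
            "ATAATA(A/C)T", "GGAACACT", "GGGGCGCC", "GTA(A/G)TACT"
        }
        assert by_label["ATAATA(A/C)T"].count == 42
        assert by_label["GGAACACT"].count == 87
        assert by_label["GGGGCGCC"].count == 108
        assert by_label["GTA(A/G)TACT"].count == 75
        assert sum(g.count for g in groups) == 312

    def test_auto_merge_helper_reproduces_partition(self):
        """Similarity-based suggestions give the same four groups."""
        table = frequency_table(LY_HAPLOTYPE_FREQS, "LY", n=381)
        merges = suggest_merges(table, reference_haplotypes=NC_HAPLOTYPE_FREQS)
        assert sorted(merges) == [
            ("ATAATAAT", "ATAATACT"), ("GTAATACT", "GTAGTACT")
        ]
        spec = HaplotypeGroupingSpec(min_frequency=0.05, merge_sets=tuple(merges))
        groups = group_haplotypes(table, spec, population_size=381)
        assert sorted(g.count for g in groups) == [42, 75, 87, 108]

    def test_no_merges_keeps_common_haplotypes(self):
        table = frequency_table({"AAAA": 0.6, "CCCC": 0.4}, n=100)
        groups = group_haplotypes(table, HaplotypeGroupingSpec(), 100)
        assert {g.label for g in groups} == {"AAAA", "CCCC"}

    def test_all_rare_yields_empty_grouping(self):
        freqs = {h: 0.04 for h in ["AAAA", "CCCC", "GGGG", "TTTT"]}
        freqs["AAAA"] = 0.88
        table = frequency_table(freqs, n=100)
        groups = group_haplotypes(
            table, HaplotypeGroupingSpec(min_frequency=0.99), 100
        )
        assert groups == []

    def test_unknown_merge_member_rejected(self):
        table = frequency_table({"AAAA": 1.0}, n=10)
        spec = HaplotypeGroupingSpec(merge_sets=(("AAAA", "ZZZZ"),))
        with pytest.raises(ValueError, match="ZZZZ"):
            group_haplotypes(table, spec, 10)

    def test_hen_conservation(self):
        table = frequency_table(LY_HAPLOTYPE_FREQS, "LY", n=381)
        groups = group_haplotypes(table, HaplotypeGroupingSpec(), 381)
        assert sum(g.count for g in groups) <= 381

    def test_merged_label_notation(self):
        assert merged_label(["GTAGTACT", "GTAATACT"]) == "GTA(A/G)TACT"


class TestRestrictionDigest:
    @pytest.mark.parametrize(
        "length, cuts, expected",
        [
            (RO_AMPLICON_LENGTH, list(RO_WILDTYPE_CUTS), [85, 474]),
            (RO_AMPLICON_LENGTH, list(RO_MUTANT_CUTS), [85, 108, 366]),
            (100, [], [100]),
        ],
    )
    def test_fragment_arithmetic(self, length, cuts, expected):
        assert restriction_fragments(length, cuts) == expected

    def test_fragments_conserve_length(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            length = int(rng.integers(50, 2000))
            n_cuts = int(rng.integers(0, 6))
            cuts = sorted(rng.choice(np.arange(1, length), size=n_cuts,
                                     replace=False).tolist())
            frags = restriction_fragments(length, cuts)
            assert sum(frags) == length

    @pytest.mark.parametrize("cuts", [[0], [559], [600], [85, 85], [451, 85]])
    def test_invalid_cut_positions_rejected(self, cuts):
        with pytest.raises(ValueError):
            restriction_fragments(559, cuts)


def test_genotype_to_frequency_round_trip():
    """Calling haplotypes on simulated genotypes reproduces the draws."""
    genotypes = simulate_genotypes(NC_HAPLOTYPE_FREQS, n_females=91, seed=5)
    haps = call_hemizygous_haplotypes(genotypes)
    assert len(haps) == 91
    table = haplotype_frequencies(haps, "NC")
    # binomial 99% bound on the leading haplotype frequency
    p = NC_HAPLOTYPE_FREQS["ATAATAAC"]
    bound = 2.58 * np.sqrt(p * (1 - p) / 91)
    leading = table.set_index("haplotype").loc["ATAATAAC", "frequency"]
    assert abs(leading - p) < bound + 1e-12
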