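"""Z-chromosome haplotype analysis: calling, frequencies, grouping, digest.

Hens are ZW, so each female's haplotype over the 8 VLDLR tag-SNP sites is
read directly off her hemizygous genotype.  This example simulates a
381-hen indigenous population at the published haplotype frequencies,
re-estimates the frequencies, collapses them into association groups
(frequency >= 5%, highly similar haplotypes merged), and runs the in-silico
PCR-RFLP digest used to screen for the egg-laying-null RO mutation.
"""

from laycurve import (
    HaplotypeGroupingSpec,
    call_hemizygous_haplotypes,
    group_haplotypes,
    haplotype_frequencies,
    restriction_fragments,
    simulate_genotypes,
    suggest_merges,
)
from laycurve.datasets import (
    LY_HAPLOTYPE_FREQS,
    NC_HAPLOTYPE_FREQS,
    RO_AMPLICON_LENGTH,
    RO_MUTANT_CUTS,
    RO_WILDTYPE_CUTS,
)
from laycurve.haplotypes import frequency_table

genotypes = simulate_genotypes(LY_HAPLOTYPE_FREQS, n_females=381, seed=11,
                               tol=2e-3)
haplotypes = call_hemizygous_haplotypes(genotypes)
table = haplotype_frequencies(haplotypes, population="LY")
print("estimated haplotype frequencies (top 6):")
print(table.head(6).to_string(index=False))

published = frequency_table(LY_HAPLOTYPE_FREQS, "LY", n=381)
merges = suggest_merges(published, reference_haplotypes=NC_HAPLOTYPE_FREQS)
print(f"\nsuggested merges of highly similar haplotypes: {merges}")
groups = group_haplotypes(published, HaplotypeGroupingSpec(merge_sets=tuple(merges)),
                          population_size=381)
print("association groups (label, hens):")
for g in groups:
    print(f"  {g.label:>14s}  {g.count:3d} hens  (members: {', '.join(g.members)})")
print(f"total grouped hens: {sum(g.count for g in groups)} of 381")

wt = restriction_fragments(RO_AMPLICON_LENGTH, list(RO_WILDTYPE_CUTS))
mut = restriction_fragments(RO_AMPLICON_LENGTH, list(RO_MUTANT_CUTS))
print(f"\nRO screen (Eco57I digest of the {RO_AMPLICON_LENGTH} bp amplicon):")
print(f"  wild-type bands: {wt} bp — what a gel of a mutation-free flock shows")
print(f"  RO-cut allele:   {mut} bp")
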