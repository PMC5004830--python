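"""Published study tables used as inputs.

Small constants a user needs to rerun the analyses: the eight chromosome-Z
tag-SNP sites of the VLDLR gene (galGal4 coordinates, 1-based), the observed
haplotype frequency distributions in the three breeds (Lueyang n=381, Nick
Chick n=91, Lohmann Brown n=50), and the RO-mutation PCR-RFLP digest layout.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TagSnpSite:
    """One genotyped tag-SNP site on chromosome Z (VLDLR region)."""

    dbsnp_id: str  # dbSNP accession, or 'novel_<pos>' for unreported SNPs
    position: int  # chrZ coordinate, galGal4, 1-based
    location: str  # gene feature
    ref: str
    alt: str


TAG_SNP_SITES: tuple[TagSnpSite, ...] = (
    TagSnpSite("rs312633123", 26419086, "intron 1", "G", "A"),
    TagSnpSite("novel_26420908", 26420908, "intron 2", "T", "G"),
    TagSnpSite("novel_26423124", 26423124, "intron 4", "A", "G"),
    TagSnpSite("rs317219970", 26424657, "exon 6 (synonymous)", "G", "A"),
    TagSnpSite("rs317314828", 26426398, "intron 10", "T", "C"),
    TagSnpSite("rs314567990", 26427922, "intron 14", "A", "G"),
    TagSnpSite("rs14777635", 26429604, "intron 15", "A", "C"),
    TagSnpSite("rs314284862", 26431186, "3' UTR", "C", "T"),
)

SITE_ORDER: tuple[str, ...] = tuple(s.dbsnp_id for s in TAG_SNP_SITES)

# Haplotype frequency distributions over the 8 tag sites, by breed.
LY_HAPLOTYPE_FREQS: dict[str, float] = {
    "GGGGCGCC": 0.283,
    "GGAACACT": 0.228,
    "GTAGTACT": 0.108,
    "GTAATACT": 0.089,
    "ATAATAAT": 0.079,
    "GGGACGCC": 0.042,
    "GGGGCACT": 0.024,
    "ATAATACT": 0.032,
    "GGGGCGCT": 0.018,
    "GGGACGCT": 0.021,
    "GTAGTAAT": 0.018,
    "GTAGTACC": 0.018,
    "GGAGCGCC": 0.018,
    "GGAACGCC": 0.021,
}

NC_HAPLOTYPE_FREQS: dict[str, float] = {
    "ATAATAAC": 0.66,
    "ATAACAAC": 0.34,
}

LOHB_HAPLOTYPE_FREQS: dict[str, float] = {
    "ATAACAAC": 0.925,
    "ATAACACC": 0.05,
    "ATGACACC": 0.025,
}

POPULATION_SIZES: dict[str, int] = {"LY": 381, "NC": 91, "LohB": 50}

# Laying-curve parameter estimates for the two recorded breeds (point
# estimates used as simulation ground truths).
CURVE_ESTIMATES: dict[str, dict[str, dict[str, float]]] = {
    "NC": {
        "segpoly": {"p": 0.89, "s": 0.002, "tp": 23.3, "tip": 6.9},
        "yang": {"a": 0.96, "c": 1.00, "x": 0.003, "d": 19.9},
        "persistency": {"yp": 0.88, "t1": 17.5, "t2": 22.2, "P": 18.5, "b4": -0.008},
    },
    "LY": {
        "segpoly": {"p": 0.53, "s": 0.008, "tp": 25.1, "tip": 4.6},
        "yang": {"a": 0.85, "c": 1.50, "x": 0.018, "d": 22.8},
        "persistency": {"yp": 0.53, "t1": 21.4, "t2": 24.3, "P": 0.0, "b4": -0.008},
    },
}

# RO-mutation PCR-RFLP: a 559 bp amplicon with Eco57I sites at 85 and 451 bp.
# Wild-type birds carry only the 85 bp site (bands 85 + 474); RO carriers gain
# the 451 bp site.
RO_AMPLICON_LENGTH = 559
RO_WILDTYPE_CUTS = (85,)
RO_MUTANT_CUTS = (85, 451)
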