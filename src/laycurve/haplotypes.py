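"""Z-chromosome haplotype analysis for hemizygous hens.

Hens are the heterogametic sex (ZW), so a female carries a single Z and her
haplotype over the tag-SNP sites is read directly off her genotype calls —
no statistical phasing is involved.  Males (ZZ) are excluded from haplotype
calling.

Provides haplotype frequency tables, positionwise (Hamming) similarity,
grouping of haplotypes for association testing (frequency threshold plus
explicit merges, with an optional similarity-based merge suggester), and the
exact fragment arithmetic of an in-silico restriction digest (PCR-RFLP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SITE_ORDER


class GenotypeDataError(ValueError):
    """Raised on malformed genotype calls (heterozygous female, bad site set)."""


@dataclass(frozen=True)
class HaplotypeGroupingSpec:
    """Configuration for collapsing a haplotype table into analysis groups.

    min_frequency : haplotypes below this are dropped unless captured by a
        merge (default 0.05).
    merge_sets : explicit collections of haplotypes to combine; sub-threshold
        members of a merge are retained inside the merged group.
    """

    min_frequency: float = 0.05
    merge_sets: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.min_frequency <= 1.0:
            raise ValueError("min_frequency must be in [0, 1]")


@dataclass
class HaplotypeGroup:
    label: str
    members: tuple[str, ...]
    frequency: float
    count: int


def call_hemizygous_haplotypes(genotypes: pd.DataFrame,
                               site_order=SITE_ORDER,
                               sex_column: str = "sex") -> pd.Series:
    """Read one haplotype string per female from hemizygous Z genotypes.

    ``genotypes`` has one row per sample with a column per site (named by
    ``site_order``) holding a single allele character, plus a sex column
    ('F'/'M').  Males are excluded (logged); females with a missing call are
    dropped with a count in the warning; a multi-character (heterozygous)
    call in a female is a data error naming the sample and site.

    Returns a Series of haplotype strings indexed by sample id.
    """
    missing_cols = [s for s in site_order if s not in genotypes.columns]
    if missing_cols:
        raise KeyError(f"genotype table missing site column(s): {missing_cols}")
    df = genotypes
    if sex_column in df.columns:
        males = df[df[sex_column].astype(str).str.upper().str.startswith("M")]
        if len(males):
            warnings.warn(
                f"excluding {len(males)} male (ZZ) sample(s) from haplotype calling",
                stacklevel=2,
            )
        df = df[~df.index.isin(males.index)]
    if len(df) == 0:
        warnings.warn("no female samples; returning empty haplotype set", stacklevel=2)
        return pd.Series([], dtype=object)

    haplotypes = {}
    n_dropped = 0
    for sample, row in df.iterrows():
        alleles = []
        ok = True
        for site in site_order:
            call = row[site]
            if call is None or (isinstance(call, float) and np.isnan(call)):
                ok = False
                break
            call = str(call).strip().upper()
            if call in ("", ".", "N", "NA"):
                ok = False
                break
            if len(call) != 1:
                raise GenotypeDataError(
                    f"sample {sample!r} has a non-hemizygous call {call!r} "
                    f"at site {site}; hens carry a single Z allele"
                )
            alleles.append(call)
        if ok:
            haplotypes[sample] = "".join(alleles)
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} female(s) with missing calls", stacklevel=2
        )
    return pd.Series(haplotypes, dtype=object)


def haplotype_frequencies(haplotypes, population: str = "") -> pd.DataFrame:
    """Count/frequency table of called haplotypes, sorted by descending frequency."""
    haps = pd.Series(list(haplotypes), dtype=object)
    if len(haps) == 0:
        raise ValueError("need at least one haplotype")
    counts = haps.value_counts()
    table = pd.DataFrame(
        {
            "haplotype": counts.index,
            "population": population,
            "count": counts.to_numpy(),
            "frequency": counts.to_numpy() / counts.sum(),
        }
    ).reset_index(drop=True)
    return table


def frequency_table(freqs: dict[str, float], population: str = "",
                    n: int | None = None, tol: float = 2e-3) -> pd.DataFrame:
    """Build a HaplotypeTable-shaped frame from a {haplotype: frequency} map.

    ``tol`` allows published tables whose rounded frequencies sum slightly
    off 1 (e.g. 0.999).
    """
    total = sum(freqs.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"frequencies sum to {total}, expected 1")
    items = sorted(freqs.items(), key=lambda kv: -kv[1])
    df = pd.DataFrame(
        {
            "haplotype": [h for h, _ in items],
            "population": population,
            "count": [round(f * n) if n else np.nan for _, f in items],
            "frequency": [f for _, f in items],
        }
    )
    return df


def hamming_similarity(h1: str, h2: str) -> tuple[int, int]:
    """Positionwise matches between two equal-length haplotype strings.

    Returns (matches, length); similarity fraction is matches/length.
    """
    if len(h1) != len(h2):
        raise ValueError(f"length mismatch: {len(h1)} vs {len(h2)}")
    matches = sum(a == b for a, b in zip(h1, h2))
    return matches, len(h1)


def _mismatches(h1: str, h2: str) -> int:
    m, L = hamming_similarity(h1, h2)
    return L - m


def merged_label(members) -> str:
    """IUPAC-style slash label: differing sites become (X/Y) with sorted alleles."""
    members = sorted(members)
    L = len(members[0])
    parts = []
    for i in range(L):
        alleles = sorted({h[i] for h in members})
        parts.append(alleles[0] if len(alleles) == 1 else "(" + "/".join(alleles) + ")")
    return "".join(parts)


def group_haplotypes(table: pd.DataFrame, spec: HaplotypeGroupingSpec,
                     population_size: int) -> list[HaplotypeGroup]:
    """Collapse a haplotype frequency table into association-analysis groups.

    Explicit merge sets are united first (their sub-threshold members are
    retained), then remaining singleton haplotypes below ``min_frequency``
    are discarded.  Group hen counts are round(Σ member frequency × N).
    """
    freqs = dict(zip(table["haplotype"], table["frequency"]))
    for mset in spec.merge_sets:
        unknown = [h for h in mset if h not in freqs]
        if unknown:
            raise ValueError(f"merge set contains unknown haplotype(s): {unknown}")
    merged_members: set[str] = set()
    groups: list[HaplotypeGroup] = []
    for mset in spec.merge_sets:
        members = tuple(sorted(mset))
        f = sum(freqs[h] for h in members)
        groups.append(
            HaplotypeGroup(merged_label(members), members, f,
                           round(f * population_size))
        )
        merged_members.update(members)
    for hap, f in freqs.items():
        if hap in merged_members:
            continue
        if f >= spec.min_frequency:
            groups.append(HaplotypeGroup(hap, (hap,), f, round(f * population_size)))
    if not groups:
        warnings.warn("no haplotype group survives the frequency threshold",
                      stacklevel=2)
    groups.sort(key=lambda g: -g.frequency)
    kept = sum(g.frequency for g in groups)
    if kept < 1.0 - 1e-9:
        warnings.warn(
            f"{1 - kept:.3f} of haplotype frequency discarded by grouping",
            stacklevel=2,
        )
    return groups


def suggest_merges(table: pd.DataFrame, reference_haplotypes,
                   min_frequency: float = 0.05,
                   max_mismatch: int = 1,
                   reference_max_mismatch: int = 2) -> list[tuple[str, ...]]:
    """Suggest merge sets of highly similar haplotypes.

    The intended association contrast is "reference-like vs other", so the
    merge classes never cross that boundary.  Reference-like haplotypes
    (<= ``reference_max_mismatch`` mismatches from any reference-panel
    haplotype, e.g. the fixed haplotypes of a selected breed) are candidates
    regardless of frequency; other haplotypes are candidates only when
    common (frequency >= ``min_frequency``).  Within each class, candidates
    at <= ``max_mismatch`` mismatches are merged by connected components;
    only multi-member components are returned.
    """
    freqs = dict(zip(table["haplotype"], table["frequency"]))

    def ref_like(h):
        return any(_mismatches(h, r) <= reference_max_mismatch
                   for r in reference_haplotypes)

    merges = []
    for in_class in (True, False):
        candidates = [
            h for h, f in freqs.items()
            if ref_like(h) == in_class and (in_class or f >= min_frequency)
        ]
        parent = {h: h for h in candidates}

        def find(h):
            while parent[h] != h:
                parent[h] = parent[parent[h]]
                h = parent[h]
            return h

        for i, h1 in enumerate(candidates):
            for h2 in candidates[i + 1:]:
                if _mismatches(h1, h2) <= max_mismatch:
                    parent[find(h1)] = find(h2)
        comps: dict[str, list[str]] = {}
        for h in candidates:
            comps.setdefault(find(h), []).append(h)
        merges.extend(tuple(sorted(v)) for v in comps.values() if len(v) > 1)
    return merges


def restriction_fragments(amplicon_length: int, cut_positions) -> list[int]:
    """Fragment lengths (bp, ascending) of an in-silico restriction digest.

    ``cut_positions`` are offsets from the 5' end, strictly increasing and
    inside (0, amplicon_length).  The fragments always sum to the amplicon
    length.
    """
    cuts = list(cut_positions)
    if any(not 0 < c < amplicon_length for c in cuts):
        raise ValueError(
            f"cut positions must lie strictly inside (0, {amplicon_length})"
        )
    if sorted(set(cuts)) != cuts:
        raise ValueError("cut positions must be strictly increasing and unique")
    edges = [0] + cuts + [amplicon_length]
    return sorted(b - a for a, b in zip(edges[:-1], edges[1:]))
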