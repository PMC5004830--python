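"""Relative qPCR quantification and group tests.

Expression is quantified by the comparative-Ct (2^-ΔΔCt) method: replicate
Cts are averaged per sample and gene, ΔCt = Ct_target - Ct_reference, ΔΔCt
subtracts the calibrator group's mean ΔCt, and the fold change is 2^-ΔΔCt
(one PCR cycle of advantage doubles the estimated template).  The calibrator
group's geometric-mean fold is exactly 1 by construction.

Group differences are assessed by classical one-way ANOVA followed by
Duncan's multiple range test, whose critical values are computed from the
studentized range distribution at the protected level
alpha_k = 1 - (1 - alpha)^(k-1) — no table lookups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FoldChangeResult:
    """Per-sample ΔCt/ΔΔCt/fold values and per-group summaries."""

    calibrator_group: str
    tissue: str
    per_sample: pd.DataFrame  # sample, group, dct, ddct, fold
    per_group: pd.DataFrame  # group, n, mean_fold, sd_fold

    @property
    def calibrator_mean_dct(self) -> float:
        cal = self.per_sample[self.per_sample["group"] == self.calibrator_group]
        return float(cal["dct"].mean())


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p_value: float
    ms_within: float
    df_between: int
    df_within: int


@dataclass
class DuncanResult:
    """Ranked means with step-down range decisions and a letter display."""

    order: list  # group labels, descending mean
    means: np.ndarray
    letters: dict  # group -> letter string
    separated_pairs: list  # (group_hi, group_lo) declared different
    critical_ranges: dict  # span k -> critical range
    alpha: float

    def any_separation(self) -> bool:
        return len(self.separated_pairs) > 0


REQUIRED_PLATE_COLUMNS = ("sample", "group", "tissue", "gene", "ct")


def fold_change_ddct(plate: pd.DataFrame, calibrator_group: str,
                     tissue: str, target_gene: str | None = None,
                     reference_gene: str | None = None) -> FoldChangeResult:
    """Relative expression of each sample by the 2^-ΔΔCt method.

    ``plate`` columns: sample, group, tissue, gene, ct (one row per technical
    replicate).  If the gene names are not given, the reference gene defaults
    to 'GAPDH' when present, otherwise the plate must contain exactly two
    genes and the non-reference one is the target.  Samples missing either
    gene are excluded with a warning.
    """
    missing = [c for c in REQUIRED_PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise KeyError(f"Ct plate missing column(s): {missing}")
    sub = plate[plate["tissue"] == tissue]
    if len(sub) == 0:
        raise ValueError(f"no rows for tissue {tissue!r}")
    genes = sorted(pd.unique(sub["gene"]))
    if reference_gene is None:
        reference_gene = "GAPDH" if "GAPDH" in genes else genes[-1]
    if target_gene is None:
        others = [g for g in genes if g != reference_gene]
        if len(others) != 1:
            raise ValueError(
                f"cannot infer target gene among {genes}; pass target_gene"
            )
        target_gene = others[0]
    if (sub["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    mean_ct = (
        sub.groupby(["sample", "group", "gene"])["ct"].mean().unstack("gene")
    )
    have_both = mean_ct[[target_gene, reference_gene]].notna().all(axis=1)
    if (~have_both).any():
        warnings.warn(
            f"excluding {int((~have_both).sum())} sample(s) missing a gene",
            stacklevel=2,
        )
        mean_ct = mean_ct[have_both]
    mean_ct = mean_ct.reset_index()
    if calibrator_group not in set(mean_ct["group"]):
        raise ValueError(
            f"calibrator group {calibrator_group!r} absent from tissue {tissue!r}"
        )
    per_sample = pd.DataFrame(
        {
            "sample": mean_ct["sample"],
            "group": mean_ct["group"],
            "dct": mean_ct[target_gene] - mean_ct[reference_gene],
        }
    )
    cal_mean = per_sample.loc[
        per_sample["group"] == calibrator_group, "dct"
    ].mean()
    per_sample["ddct"] = per_sample["dct"] - cal_mean
    per_sample["fold"] = 2.0 ** (-per_sample["ddct"])
    per_group = (
        per_sample.groupby("group")["fold"]
        .agg(n="count", mean_fold="mean", sd_fold="std")
        .reset_index()
    )
    return FoldChangeResult(
        calibrator_group=calibrator_group,
        tissue=tissue,
        per_sample=per_sample,
        per_group=per_group,
    )


def anova_oneway(values, grouping) -> AnovaResult:
    """Classical one-way ANOVA decomposition.

    Returns the F statistic, its p-value, and the within-group (residual)
    mean square and degrees of freedom needed by Duncan's test.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    labels = pd.unique(grouping)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    groups = [values[grouping == g] for g in labels]
    sizes = np.array([len(g) for g in groups])
    if np.any(sizes < 2):
        small = [str(l) for l, s in zip(labels, sizes) if s < 2]
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    grand = values.mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_between = len(labels) - 1
    df_within = len(values) - len(labels)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f = 0.0 if ms_between == 0.0 else np.inf
    else:
        f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), p, ms_within, df_between, df_within)


def duncan_mrt(group_means, group_sizes, residual_ms: float, df: int,
               alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test on ranked group means.

    For a stretch of k ranked means the critical range is
    q(1 - alpha_k; k, df) * sqrt(MS_within / n_h) with protection level
    alpha_k = 1 - (1-alpha)^(k-1), n_h the (harmonic-mean) group size and q
    the studentized range quantile.  Standard step-down blocking applies: a
    stretch whose extremes do not differ is declared homogeneous and no pair
    inside it is separated.  Letter groups are emitted for display.
    """
    if df < 1:
        raise ValueError("residual df must be >= 1")
    means = pd.Series(dict(group_means)) if not isinstance(group_means, pd.Series) else group_means
    sizes = dict(group_sizes)
    order = list(means.sort_values(ascending=False).index)
    m = means[order].to_numpy(dtype=float)
    G = len(order)
    n_h = G / sum(1.0 / sizes[g] for g in order)  # harmonic mean size
    se = np.sqrt(residual_ms / n_h)

    crit = {}
    for k in range(2, G + 1):
        alpha_k = 1.0 - (1.0 - alpha) ** (k - 1)
        crit[k] = float(stats.studentized_range.ppf(1.0 - alpha_k, k, df) * se)

    # step-down: different[i][j] for i<j among ranked means
    different = np.zeros((G, G), dtype=bool)
    homogeneous = np.zeros((G, G), dtype=bool)  # stretch [i..j] declared equal
    for span in range(G, 1, -1):
        for i in range(0, G - span + 1):
            j = i + span - 1
            if any(homogeneous[a][b] for a in range(0, i + 1)
                   for b in range(j, G) if (a, b) != (i, j) and b - a >= span):
                homogeneous[i][j] = True
                continue
            if m[i] - m[j] > crit[span]:
                different[i][j] = True
            else:
                homogeneous[i][j] = True

    separated = [
        (order[i], order[j]) for i in range(G) for j in range(i + 1, G)
        if different[i][j]
    ]

    # letters: maximal homogeneous stretches cover the ranked list
    runs = []
    for i in range(G):
        j = i
        while j + 1 < G and not different[i][j + 1]:
            j += 1
        runs.append((i, j))
    maximal = [r for r in runs if not any(
        (a <= r[0] and r[1] <= b and (a, b) != r) for a, b in runs)]
    letters = {g: "" for g in order}
    for idx, (a, b) in enumerate(sorted(maximal)):
        ch = chr(ord("a") + idx)
        for pos in range(a, b + 1):
            letters[order[pos]] += ch

    return DuncanResult(
        order=order,
        means=m,
        letters=letters,
        separated_pairs=separated,
        critical_ranges=crit,
        alpha=alpha,
    )
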