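"""Synthetic data generators emulating the study designs.

Every analysis stage can be exercised without real data:

* egg records — hen-week laying counts from a chosen curve family, recorded
  over weeks 17-50 of age; the default noise is Binomial(7, rate) because an
  observed weekly rate is a 7-day egg count divided by 7.  A Gaussian-on-rate
  mode exists to emulate the least-squares error assumptions exactly (its
  "eggs" column is then fractional, = rate*7).
* genotypes — hemizygous Z haplotypes drawn from a frequency table and spelt
  out as per-site allele calls for female (ZW) birds.
* qPCR plates — reference-gene Cts around a fixed baseline plus group-level
  ΔCt offsets and replicate noise, in the study's 6-samples x 3-replicates
  layout.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SITE_ORDER
from .nls_fit import get_family
from .records import DEFAULT_WEEK_WINDOW


@dataclass(frozen=True)
class SimulationConfig:
    """Recipe for synthetic hen-week egg records.

    group_params maps group label -> parameter vector (sequence or dict in
    the family's parameter order); n_hens maps group label -> hen count.
    noise is 'binomial' (eggs ~ Binomial(7, rate), the default) or
    'gaussian' (rate + N(0, sd), clamped to [0,1], kept continuous).
    """

    family: str
    group_params: dict
    n_hens: dict
    weeks: tuple[int, int] = DEFAULT_WEEK_WINDOW
    noise: str = "binomial"
    gaussian_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise not in ("binomial", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")
        if set(self.group_params) != set(self.n_hens):
            raise ValueError("group_params and n_hens must share group labels")


def _theta(fam, params):
    if isinstance(params, dict):
        return np.array([params[name] for name in fam.param_names], dtype=float)
    return np.asarray(params, dtype=float)


def simulate_egg_records(config: SimulationConfig) -> pd.DataFrame:
    """Draw a hen-week egg-record table per the configuration.

    The true weekly rate is the group's curve clamped into [0, 1]; each
    hen-week is dropped independently with probability ``missing_rate``.
    Deterministic under the config seed.
    """
    fam = get_family(config.family)
    rng = np.random.default_rng(config.seed)
    weeks = np.arange(config.weeks[0], config.weeks[1] + 1)
    frames = []
    hen_counter = 0
    for group in sorted(config.group_params):
        theta = _theta(fam, config.group_params[group])
        n = int(config.n_hens[group])
        rate_true = np.clip(np.asarray(fam.evaluate(weeks, theta), dtype=float), 0.0, 1.0)
        week_grid = np.tile(weeks, n)
        hen_grid = np.repeat(np.arange(hen_counter, hen_counter + n), weeks.size)
        hen_counter += n
        truth = np.tile(rate_true, n)
        if config.noise == "binomial":
            eggs = rng.binomial(7, truth).astype(float)
        else:
            noisy = truth + rng.normal(0.0, config.gaussian_sd, truth.size) \
                if config.gaussian_sd > 0 else truth
            eggs = np.clip(noisy, 0.0, 1.0) * 7.0
        keep = np.ones(eggs.size, dtype=bool)
        if config.missing_rate > 0:
            keep = rng.random(eggs.size) >= config.missing_rate
        frames.append(
            pd.DataFrame(
                {
                    "hen_id": [f"hen{h:05d}" for h in hen_grid[keep]],
                    "group": group,
                    "week": week_grid[keep],
                    "eggs": eggs[keep],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["rate"] = df["eggs"] / 7.0
    return df


def simulate_genotypes(hap_freqs: dict[str, float], n_females: int,
                       seed: int = 0, site_order=SITE_ORDER,
                       population: str = "sim", tol: float = 1e-6) -> pd.DataFrame:
    """Draw one Z haplotype per female and spell it out as per-site calls.

    Returns a genotype table with sample ids as index, a 'sex' column (all
    'F') and one single-character allele column per site.  Frequencies must
    sum to 1 within ``tol`` (pass a looser tolerance for published tables
    rounded to three decimals); they are renormalised before drawing.
    """
    haps = list(hap_freqs)
    freqs = np.array([hap_freqs[h] for h in haps], dtype=float)
    if abs(freqs.sum() - 1.0) > tol:
        raise ValueError(f"haplotype frequencies sum to {freqs.sum()}, expected 1")
    if any(len(h) != len(site_order) for h in haps):
        raise ValueError("haplotype length must match the number of sites")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(haps), size=n_females, p=freqs / freqs.sum())
    rows = []
    for i, k in enumerate(draws):
        row = {"sex": "F", "population": population}
        for j, site in enumerate(site_order):
            row[site] = haps[k][j]
        rows.append(row)
    return pd.DataFrame(rows, index=[f"{population}_F{i:04d}" for i in range(n_females)])


def simulate_qpcr(group_dct_means: dict[str, float], replicate_sd: float,
                  n_samples: int = 6, n_replicates: int = 3, seed: int = 0,
                  tissue: str = "ovary", baseline_ct: float = 18.0,
                  target_gene: str = "VLDLR",
                  reference_gene: str = "GAPDH") -> pd.DataFrame:
    """Draw a Ct plate with group-level ΔCt offsets and replicate noise.

    Per sample, the reference gene's true Ct sits at ``baseline_ct`` and the
    target's at baseline + group ΔCt; each technical replicate adds
    N(0, replicate_sd) noise.  Deterministic under the seed.
    """
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(group_dct_means):
        dct = group_dct_means[group]
        for s in range(n_samples):
            sample = f"{group}_s{s}"
            for gene, true_ct in ((reference_gene, baseline_ct),
                                  (target_gene, baseline_ct + dct)):
                noise = (rng.normal(0.0, replicate_sd, n_replicates)
                         if replicate_sd > 0 else np.zeros(n_replicates))
                for r in range(n_replicates):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "tissue": tissue,
                            "gene": gene,
                            "replicate": r + 1,
                            "ct": true_ct + noise[r],
                        }
                    )
    return pd.DataFrame(rows)
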