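"""File I/O, validation and the end-to-end pipeline.

All tabular inputs are delimited text (comma or tab, auto-detected):

* egg records — header ``hen_id,group,week,eggs``;
* genotypes — one row per sample, a ``sample`` id column, optional ``sex``,
  and one single-allele column per tag site;
* Ct plates — header ``sample,group,tissue,gene,replicate,ct``.

`run_pipeline` ties the stages together (simulate/fit/GOF/compare) and
writes human-readable reports plus a machine-readable JSON summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import TAG_SNP_SITES
from .gof import gof_report
from .group_compare import delta_par, format_p_value, ssrt_test
from .nls_fit import FAMILIES, fit_model, get_family
from .records import DEFAULT_WEEK_WINDOW, validate_egg_records

logger = logging.getLogger("laycurve")


@dataclass
class ReadReport:
    """Row-level validation outcome of a records file."""

    n_read: int
    n_kept: int
    rejections: dict = field(default_factory=dict)  # reason -> count


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_egg_records(path, week_window=DEFAULT_WEEK_WINDOW,
                     return_report: bool = False):
    """Read and validate an egg-record file.

    Rows outside the week window or with eggs outside [0, 7] are rejected;
    the per-reason rejection counts are available via ``return_report``.
    """
    df = _read_delimited(path)
    required = ("hen_id", "group", "week", "eggs")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"egg-record file {path} missing column(s): {missing}")
    n_read = len(df)
    rejections = {}
    eggs = pd.to_numeric(df["eggs"], errors="coerce")
    week = pd.to_numeric(df["week"], errors="coerce")
    bad_parse = eggs.isna() | week.isna()
    bad_eggs = ~bad_parse & ((eggs < 0) | (eggs > 7))
    lo, hi = week_window
    bad_week = ~bad_parse & ~bad_eggs & ((week < lo) | (week > hi))
    for name, mask in (("unparseable", bad_parse), ("eggs_out_of_range", bad_eggs),
                       ("week_out_of_window", bad_week)):
        if int(mask.sum()):
            rejections[name] = int(mask.sum())
    keep = ~(bad_parse | bad_eggs | bad_week)
    out = df[keep].copy()
    out["week"] = week[keep].astype(int)
    out["eggs"] = eggs[keep]
    out = validate_egg_records(out)
    report = ReadReport(n_read=n_read, n_kept=len(out), rejections=rejections)
    if rejections:
        logger.info("read %s: kept %d/%d rows, rejections %s",
                    path, report.n_kept, n_read, rejections)
    if return_report:
        return out, report
    return out


def write_egg_records(records: pd.DataFrame, path) -> None:
    records[["hen_id", "group", "week", "eggs"]].to_csv(path, index=False)


def read_genotypes(path) -> pd.DataFrame:
    """Read a genotype table; the ``sample`` column becomes the index."""
    df = _read_delimited(path)
    if "sample" in df.columns:
        df = df.set_index("sample")
    return df


def read_ct_plate(path) -> pd.DataFrame:
    df = _read_delimited(path)
    required = ("sample", "group", "tissue", "gene", "ct")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"Ct plate file {path} missing column(s): {missing}")
    return df


def write_vcf(genotypes: pd.DataFrame, path, sites=TAG_SNP_SITES,
              assembly: str = "galGal4") -> None:
    """Export hemizygous tag-site calls as a minimal VCF v4.2 (chromosome Z).

    Female (ZW) samples are emitted with haploid genotypes.
    """
    samples = [str(s) for s in genotypes.index]
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={assembly}",
        "##contig=<ID=Z>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for site in sites:
        calls = []
        for s in genotypes.index:
            allele = str(genotypes.loc[s, site.dbsnp_id])
            if allele == site.ref:
                calls.append("0")
            elif allele == site.alt:
                calls.append("1")
            else:
                calls.append(".")
        lines.append(
            f"Z\t{site.position}\t{site.dbsnp_id}\t{site.ref}\t{site.alt}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PipelineConfig:
    """End-to-end run configuration."""

    records_path: str
    families: tuple = ("segpoly", "yang", "persistency")
    grouping: str = "group"
    reference_group: str | None = None
    alpha: float = 0.05
    week_window: tuple = DEFAULT_WEEK_WINDOW
    out_dir: str = "laycurve_out"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for fam in self.families:
            get_family(fam)  # fail fast on unknown family


def _fit_summary_dict(fit, report):
    return {
        "family": fit.family,
        "estimates": fit.estimates,
        "se": {k: (None if np.isnan(v) else float(v))
               for k, v in zip(fit.param_names, fit.se)},
        "ci95": {k: ([None, None] if np.isnan(v[0]) else [float(v[0]), float(v[1])])
                 for k, v in fit.ci95.items()},
        "sse": fit.sse,
        "df": fit.df,
        "n_records": fit.n_records,
        "converged": bool(fit.converged),
        "n_iter": fit.n_iter,
        "gof": report.as_dict(),
    }


def format_fit_table(fit, report) -> str:
    """Human-readable per-parameter report (estimate ± se with 95% CI)."""
    lines = [f"family: {fit.family}   n={fit.n_records}  sse={fit.sse:.6g}  "
             f"converged={fit.converged} ({fit.n_iter} iterations)"]
    ci = fit.ci95
    for i, name in enumerate(fit.param_names):
        est = fit.theta[i]
        if np.isnan(fit.se[i]):
            lines.append(f"  {name:>4s} = {est:.4g}  (boundary; se/CI suppressed)")
        else:
            lo, hi = ci[name]
            lines.append(
                f"  {name:>4s} = {est:.4g} ± {fit.se[i]:.4g}  ({lo:.4g}, {hi:.4g})"
            )
    g = report
    lines.append(
        f"  AIC={g.aic:.1f}  MSE={g.mse:.4g}  R2={g.r2:.3f}  "
        f"MME={g.mme:+.4g} (m={g.m_used})"
    )
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> dict:
    """Fit every family per group, evaluate GOF, and compare groups.

    Writes text reports and ``summary.json`` under ``config.out_dir`` and
    returns the summary dict.  Raises on any stage failure, naming the stage.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_repr = json.dumps(
        {k: str(v) for k, v in sorted(vars(config).items())}, sort_keys=True
    )
    cfg_hash = hashlib.sha256(cfg_repr.encode()).hexdigest()[:12]
    logger.info("pipeline start: seed=%d config_hash=%s", config.seed, cfg_hash)

    summary = {"seed": config.seed, "config_hash": cfg_hash, "groups": {},
               "comparisons": {}, "timing_s": {}}
    stage = "read"
    try:
        records = read_egg_records(config.records_path, config.week_window)
        summary["timing_s"][stage] = time.time() - t0
        groups = sorted(pd.unique(records[config.grouping]))
        report_lines = []
        stage = "fit"
        t_stage = time.time()
        for group in groups:
            sub = records[records[config.grouping] == group]
            summary["groups"][str(group)] = {}
            for fam in config.families:
                fit = fit_model(sub, fam)
                rep = gof_report(fit, sub)
                summary["groups"][str(group)][fam] = _fit_summary_dict(fit, rep)
                report_lines.append(f"== group {group} ==")
                report_lines.append(format_fit_table(fit, rep))
        summary["timing_s"][stage] = time.time() - t_stage
        stage = "compare"
        t_stage = time.time()
        if len(groups) >= 2:
            reference = config.reference_group or groups[0]
            for fam in config.families:
                res = ssrt_test(records, fam, grouping=config.grouping)
                dp = delta_par(records, fam, reference_group=reference,
                               grouping=config.grouping)
                summary["comparisons"][fam] = {
                    "f_r": res.f_r,
                    "p_value": res.p_value,
                    "p_display": res.p_display,
                    "sse_reduced": res.sse_reduced,
                    "sse_full": res.sse_full,
                    "df_reduced": res.df_reduced,
                    "df_full": res.df_full,
                    "delta_par": {
                        grp: {
                            name: {
                                "delta": float(d["delta"][i]),
                                "se": (None if np.isnan(d["se"][i])
                                       else float(d["se"][i])),
                                "ci95": ([None, None] if np.isnan(d["se"][i]) else
                                         [float(d["ci95"][i][0]),
                                          float(d["ci95"][i][1])]),
                                "significant": bool(d["significant"][i]),
                            }
                            for i, name in enumerate(dp.param_names)
                        }
                        for grp, d in dp.groups.items()
                    },
                }
                report_lines.append(
                    f"== SSRT {fam}: F={res.f_r:.4g} "
                    f"(df {res.df_reduced - res.df_full}, {res.df_full}), "
                    f"p {format_p_value(res.p_value)} =="
                )
        summary["timing_s"][stage] = time.time() - t_stage
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out_dir / "report.txt").write_text("\n".join(report_lines) + "\n")
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline done in %.2fs", time.time() - t0)
    return summary
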