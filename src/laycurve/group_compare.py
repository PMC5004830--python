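"""Group comparison of laying curves: the sum-of-squares reduction test and
per-parameter group contrasts (Δpar).

The reduced model fits one parameter set to the pooled records of all groups;
the full model gives every group its own set.  Because the full model is
estimated as a single joint problem initialised from the reduced estimates
(with the non-reference groups parameterised as reference + Δpar), the
nesting inequality SSE_full <= SSE_reduced holds by construction, and the
joint covariance directly yields standard errors for each Δpar.

F_R = [(SSE_r - SSE_f)/(df_r - df_f)] / (SSE_f/df_f), compared with the F
distribution on (df_r - df_f, df_f) degrees of freedom.  A Δpar is declared
significant when its 95% confidence interval (t quantile at the full-model
residual df) excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .nls_fit import FitOptions, ModelFit, fit_model, gauss_newton, get_family
from .records import aggregate_weekly


@dataclass(frozen=True)
class SsrtResult:
    """Extra-sum-of-squares F comparison of pooled vs per-group curve fits."""

    sse_reduced: float
    sse_full: float
    df_reduced: int
    df_full: int
    f_r: float
    p_value: float

    @property
    def p_display(self) -> str:
        return format_p_value(self.p_value)


@dataclass
class DeltaParResult:
    """Per-parameter contrasts of each group against the reference group."""

    family: str
    reference_group: str
    param_names: tuple[str, ...]
    reference_estimates: np.ndarray
    reference_se: np.ndarray
    groups: dict = field(default_factory=dict)  # group -> dict of arrays
    df: int = 0
    sse: float = 0.0
    converged: bool = True

    def table(self) -> pd.DataFrame:
        rows = []
        for grp, d in self.groups.items():
            for i, name in enumerate(self.param_names):
                rows.append(
                    {
                        "group": grp,
                        "parameter": name,
                        "estimate": d["estimate"][i],
                        "delta": d["delta"][i],
                        "se": d["se"][i],
                        "ci95_low": d["ci95"][i][0],
                        "ci95_high": d["ci95"][i][1],
                        "significant": d["significant"][i],
                    }
                )
        return pd.DataFrame(rows)


def format_p_value(p: float, floor: float = 1e-6) -> str:
    """Report very small p-values as '< 0.000001' rather than raw floats."""
    if p < floor:
        return f"< {floor:.6f}"
    return f"{p:.6g}"


def _joint_fit(records, fam, group_order, theta0_base, options):
    """Gauss-Newton over [base, delta_2, ..., delta_G]; delta_ref = 0."""
    p = fam.n_params
    G = len(group_order)
    blocks = [aggregate_weekly(records, group=g) for g in group_order]

    def unpack(theta):
        base = theta[:p]
        out = [base]
        for j in range(1, G):
            out.append(base + theta[p * j: p * (j + 1)])
        return out

    def predict(theta):
        thetas = unpack(theta)
        return [fam.evaluate(b.weeks, th) for b, th in zip(blocks, thetas)]

    def normal_terms(theta):
        thetas = unpack(theta)
        dim = p * G
        A = np.zeros((dim, dim))
        bvec = np.zeros(dim)
        for j, (blk, th) in enumerate(zip(blocks, thetas)):
            g = fam.gradient(blk.weeks, th)
            yhat = np.asarray(fam.evaluate(blk.weeks, th))
            Aj = g.T @ (g * blk.n[:, None])
            bj = g.T @ (blk.total - blk.n * yhat)
            idx = [np.arange(p)]
            if j > 0:
                idx.append(np.arange(p * j, p * (j + 1)))
            for r in idx:
                for c in idx:
                    A[np.ix_(r, c)] += Aj
                bvec[r] += bj
        return A, bvec

    def project(theta):
        base = fam.project(theta[:p])
        out = [base]
        for j in range(1, G):
            gth = fam.project(base + theta[p * j: p * (j + 1)])
            out.append(gth - base)
        return np.concatenate(out)

    theta0 = np.concatenate([theta0_base] + [np.zeros(p)] * (G - 1))
    theta, sse, converged, n_iter, trace, message = gauss_newton(
        blocks, predict, normal_terms, project, theta0, options
    )
    n_total = sum(b.n_records for b in blocks)
    df_full = n_total - p * G
    # covariance of the joint parameter vector at the solution
    A, _ = normal_terms(theta)
    try:
        cov = (sse / df_full) * np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov = np.full((p * G, p * G), np.nan)
        converged = False
    return theta, cov, sse, df_full, converged, unpack


def ssrt_test(records: pd.DataFrame, family, grouping: str = "group",
              options: FitOptions | None = None,
              return_fits: bool = False):
    """Sum-of-squares reduction test across the groups of ``records``.

    ``grouping`` names the column holding group labels.  Returns an
    :class:`SsrtResult` (optionally with the reduced fit and joint full-fit
    internals when ``return_fits``).
    """
    fam = get_family(family)
    df = records if grouping == "group" else records.assign(group=records[grouping])
    groups = sorted(pd.unique(df["group"]))
    if len(groups) < 2:
        raise ValueError("SSRT needs at least 2 groups")
    for g in groups:
        sub = df[df["group"] == g]
        if len(sub) <= fam.n_params:
            raise ValueError(
                f"group {g!r} has {len(sub)} records, too few to fit "
                f"{fam.n_params} parameters"
            )
    reduced = fit_model(df, fam, options=options)
    theta, cov, sse_full, df_full, converged, unpack = _joint_fit(
        df, fam, groups, reduced.theta, options
    )
    n_total = reduced.n_records
    df_reduced = n_total - fam.n_params
    num_df = df_reduced - df_full
    if sse_full == 0.0:
        # exact full fit: no evidence against equality unless the reduced
        # model leaves residual, in which case the F statistic diverges
        f_r = 0.0 if reduced.sse <= 1e-12 else np.inf
    else:
        f_r = max(((reduced.sse - sse_full) / num_df) / (sse_full / df_full), 0.0)
    p_value = float(stats.f.sf(f_r, num_df, df_full)) if np.isfinite(f_r) else 0.0
    result = SsrtResult(
        sse_reduced=reduced.sse,
        sse_full=sse_full,
        df_reduced=df_reduced,
        df_full=df_full,
        f_r=float(f_r),
        p_value=p_value,
    )
    if return_fits:
        return result, reduced, (theta, cov, df_full, unpack, groups)
    return result


def delta_par(records: pd.DataFrame, family, reference_group: str,
              other_groups=None, grouping: str = "group",
              options: FitOptions | None = None) -> DeltaParResult:
    """Estimate Δpar = (group parameters) - (reference parameters) with 95% CIs.

    All requested groups are compared against the reference within one joint
    reparameterized fit, so the Δpar standard errors come from the joint
    covariance.  A Δpar is flagged significant when its CI excludes zero.
    ``other_groups=None`` compares every non-reference group.
    """
    fam = get_family(family)
    df = records if grouping == "group" else records.assign(group=records[grouping])
    labels = sorted(pd.unique(df["group"]))
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} not in data")
    if other_groups is None:
        other_groups = [g for g in labels if g != reference_group]
    else:
        other_groups = list(other_groups)
        unknown = [g for g in other_groups if g not in labels]
        if unknown:
            raise ValueError(f"unknown group(s): {unknown}")
    group_order = [reference_group] + other_groups
    sub = df[df["group"].isin(group_order)]
    pooled = fit_model(sub, fam, options=options)
    theta, cov, sse, df_full, converged, unpack = _joint_fit(
        sub, fam, group_order, pooled.theta, options
    )
    p = fam.n_params
    thetas = unpack(theta)
    tq = stats.t.ppf(0.975, df_full)
    se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))

    ref_boundary = fam.boundary_mask(thetas[0])
    ref_se = se_all[:p].copy()
    ref_se[ref_boundary] = np.nan
    result = DeltaParResult(
        family=fam.name,
        reference_group=reference_group,
        param_names=fam.param_names,
        reference_estimates=thetas[0],
        reference_se=ref_se,
        df=df_full,
        sse=sse,
        converged=converged,
    )
    for j, grp in enumerate(other_groups, start=1):
        sl = slice(p * j, p * (j + 1))
        delta = theta[sl]
        se = se_all[sl].copy()
        boundary = fam.boundary_mask(thetas[j]) | ref_boundary
        se[boundary] = np.nan
        ci = [(d - tq * s, d + tq * s) for d, s in zip(delta, se)]
        significant = np.array(
            [np.isfinite(lo) and (lo > 0 or hi < 0) for lo, hi in ci]
        )
        result.groups[grp] = {
            "estimate": thetas[j],
            "delta": delta,
            "se": se,
            "ci95": ci,
            "significant": significant,
            "boundary": boundary,
        }
    return result
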