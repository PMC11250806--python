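"""Per-probe differential methylation with empirical-Bayes moderated t.

Each probe is fit with ordinary least squares against a design of
intercept, case/control status (the coefficient of interest, reported as
log2FC since on the M scale it is the log2 fold change of the methylated/
unmethylated intensity ratio), age, sex and optionally a cohort factor.
Residual variances are then shrunk across probes toward a common prior via
the standard empirical-Bayes moment-matching on log s^2 (digamma /
trigamma inversion), yielding moderated t-statistics with d0 + d degrees
of freedom.  P-values are Benjamini-Hochberg adjusted, and for pooled
analyses a directional agreement index records in what fraction of
cohorts the case-minus-control median difference shares the pooled sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import MethylationDataset

__all__ = [
    "build_design",
    "LinearFitResult",
    "fit_probewise_models",
    "moderate",
    "bh_fdr",
    "directional_agreement",
    "run_ewas",
]


def build_design(samples: pd.DataFrame, include_study_factor: bool = False,
                 covariates: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
    """Design matrix: intercept, status (0=control, 1=case), covariates,
    optionally treatment-coded batch indicators against the first batch
    (alphabetical)."""
    cols = {"intercept": np.ones(len(samples)),
            "status": (samples["status"] == "case").astype(float).to_numpy()}
    if "age" in covariates:
        cols["age"] = samples["age"].astype(float).to_numpy()
    if "sex" in covariates:
        cols["sexM"] = (samples["sex"] == "M").astype(float).to_numpy()
    if include_study_factor:
        levels = sorted(samples["batch"].unique())
        for lev in levels[1:]:
            cols[f"batch_{lev}"] = (samples["batch"] == lev).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=samples.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X.to_numpy(), list(X.columns))
        raise ValueError(f"design is rank-deficient; aliased columns: {aliased}")
    return X


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    keep, aliased = [], []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


@dataclass
class LinearFitResult:
    """Per-probe OLS summaries for the status coefficient."""

    probe_ids: list[str]
    coef: np.ndarray        # status coefficient per probe (log2FC)
    unscaled_sd: np.ndarray  # sqrt of status diagonal of (X'X)^-1
    sigma: np.ndarray       # residual SD per probe
    df_residual: int


def fit_probewise_models(ds: MethylationDataset,
                         design: pd.DataFrame) -> LinearFitResult:
    """Vectorized OLS of every probe on a shared design matrix."""
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        aliased = _aliased_columns(X, list(design.columns))
        raise ValueError(f"design is rank-deficient; aliased columns: {aliased}")
    if n <= k:
        raise ValueError("need more samples than design columns")
    Y = ds.values.to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ Y                      # k x p
    resid = Y - X @ coef
    df = n - k
    s2 = (resid ** 2).sum(axis=0) / df
    j = list(design.columns).index("status")
    u = float(np.sqrt(XtX_inv[j, j]))
    return LinearFitResult(probe_ids=ds.probe_ids, coef=coef[j],
                           unscaled_sd=np.full(Y.shape[1], u),
                           sigma=np.sqrt(s2), df_residual=df)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # starting value, good for the relevant range
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / np.maximum(y, 1e-12)) < 1e-10:
            break
    return y


def estimate_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of a scaled inverse chi-square prior to the
    ensemble of residual variances via the distribution of log s^2."""
    sigma2 = np.asarray(sigma2, dtype=float)
    ok = sigma2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero: degenerate data")
    z = np.log(sigma2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (n - 1) if n > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(np.array([excess]))[0]
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                            - np.log(d0 / 2.0)))
    else:
        # no excess dispersion beyond sampling noise: infinite prior df;
        # the prior variance is the geometric mean of the observed s^2 so
        # that identical residual variances shrink to themselves exactly
        d0 = np.inf
        s0_2 = float(np.exp(z.mean()))
    return d0, s0_2


def moderate(fit: LinearFitResult) -> pd.DataFrame:
    """Empirical-Bayes variance shrinkage and moderated t per probe.

    Returns the DM table with columns logFC, SE, t, P.Value, adj.P.Val
    plus table-level attributes ``d0`` and ``s0_2`` in ``attrs``.
    """
    if len(fit.probe_ids) < 10:
        raise ValueError("need >= 10 probes to estimate the variance prior")
    s2 = fit.sigma ** 2
    d = fit.df_residual
    d0, s0_2 = estimate_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = fit.unscaled_sd * np.sqrt(s2_post)
    t = fit.coef / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)
    table = pd.DataFrame({"logFC": fit.coef, "SE": se, "t": t,
                          "P.Value": p, "adj.P.Val": q},
                         index=pd.Index(fit.probe_ids, name="probe_id"))
    table.attrs["d0"] = d0
    table.attrs["s0_2"] = s0_2
    table.attrs["df_residual"] = d
    return table


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def directional_agreement(per_cohort_median_diffs: pd.DataFrame,
                          reference_sign) -> pd.Series:
    """Fraction of cohorts whose case-minus-control median difference has
    the reference sign; exact zeros count as disagreement."""
    diffs = per_cohort_median_diffs
    ref = np.sign(np.asarray(reference_sign, dtype=float))
    signs = np.sign(diffs.to_numpy(dtype=float))
    match = (signs == ref[:, None]) & (signs != 0)
    return pd.Series(match.mean(axis=1), index=diffs.index, name="agreement")


def median_diffs_by_cohort(ds: MethylationDataset) -> pd.DataFrame:
    """Per-probe case-minus-control median methylation, one column per
    cohort batch."""
    out = {}
    for b in pd.unique(ds.samples["batch"]):
        sub = ds.values[(ds.samples["batch"] == b).to_numpy()]
        status = ds.samples.loc[sub.index, "status"]
        cases = sub[(status == "case").to_numpy()]
        ctrls = sub[(status == "control").to_numpy()]
        if len(cases) == 0 or len(ctrls) == 0:
            continue
        out[b] = cases.median(axis=0) - ctrls.median(axis=0)
    return pd.DataFrame(out)


def run_ewas(ds: MethylationDataset, include_study_factor: bool = False,
             covariates: tuple[str, ...] = ("age", "sex"),
             with_agreement: bool = None) -> pd.DataFrame:
    """Differential methylation: design, per-probe fit, moderation, FDR.

    In pooled mode (``include_study_factor=True``) the directional
    agreement index against the pooled effect sign is appended.
    """
    design = build_design(ds.samples, include_study_factor=include_study_factor,
                          covariates=covariates)
    fit = fit_probewise_models(ds, design)
    table = moderate(fit)
    if with_agreement is None:
        with_agreement = include_study_factor
    if with_agreement:
        diffs = median_diffs_by_cohort(ds)
        table["agreement"] = directional_agreement(
            diffs, np.sign(table["logFC"].to_numpy()))
    return table
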