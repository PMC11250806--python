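"""Random-effects meta-analysis of per-cohort probe effects.

Per probe, the k cohort log2FC estimates y_i with sampling variances
v_i = SE_i^2 are combined under the random-effects model
y_i ~ N(mu, v_i + tau^2).  Between-study variance tau^2 uses the
Sidik-Jonkman estimator; the pooled effect is the inverse-variance
weighted mean with Wald (normal) inference; heterogeneity is summarized
by Cochran's Q (fixed-effect weights) and I^2 on the conventional
"typical within-study variance" scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr

__all__ = [
    "sidik_jonkman_tau2",
    "random_effects_meta",
    "meta_ewas",
    "overlap_analysis",
]

log = logging.getLogger(__name__)


def sidik_jonkman_tau2(y, v) -> float:
    """Sidik-Jonkman between-study variance estimator.

    tau0^2 = sum((y - ybar)^2)/k with the unweighted mean; provisional
    weights w_i = 1/(v_i/tau0^2 + 1); tau^2 = sum(w (y - mu_w)^2)/(k-1).
    Returns 0 when the effects show no dispersion at all.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = y.size
    if k < 2:
        raise ValueError("need at least 2 studies")
    if np.any(v <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("variances must be positive and effects finite")
    tau0_2 = np.sum((y - y.mean()) ** 2) / k
    if tau0_2 == 0:
        return 0.0
    r = v / tau0_2
    w = 1.0 / (r + 1.0)
    mu_w = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - mu_w) ** 2) / (k - 1))


def random_effects_meta(y, v) -> dict:
    """One probe's random-effects pooled estimate and heterogeneity.

    Returns a dict with mu, se, zval, pval, tau2, I2 (percent), Q, k.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = y.size
    tau2 = sidik_jonkman_tau2(y, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = mu / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    # Cochran Q with fixed-effect weights
    w_fe = 1.0 / v
    mu_fe = np.sum(w_fe * y) / np.sum(w_fe)
    Q = float(np.sum(w_fe * (y - mu_fe) ** 2))
    # I^2 against the typical within-study variance s~^2
    s_tilde2 = (k - 1) * np.sum(w_fe) / (np.sum(w_fe) ** 2 - np.sum(w_fe ** 2))
    I2 = float(100.0 * tau2 / (tau2 + s_tilde2)) if tau2 + s_tilde2 > 0 else 0.0
    return {"mu": mu, "se": se, "zval": z, "pval": max(p, np.finfo(float).tiny),
            "tau2": tau2, "I2": I2, "Q": Q, "k": int(k)}


def meta_ewas(per_cohort_tables: list[pd.DataFrame],
              inclusion_alpha: float = 0.05) -> pd.DataFrame:
    """Meta-analyze per-cohort DM tables probe by probe.

    Probes nominally significant (p < ``inclusion_alpha``) in at least one
    cohort are included; probes observed in fewer than two cohorts are
    skipped with a log entry.  Meta p-values are BH-adjusted over the
    included set.
    """
    if not per_cohort_tables:
        raise ValueError("no cohort tables supplied")
    eff = pd.concat([t["logFC"] for t in per_cohort_tables], axis=1,
                    keys=range(len(per_cohort_tables)))
    var = pd.concat([t["SE"] ** 2 for t in per_cohort_tables], axis=1,
                    keys=range(len(per_cohort_tables)))
    pv = pd.concat([t["P.Value"] for t in per_cohort_tables], axis=1,
                   keys=range(len(per_cohort_tables)))
    include = (pv < inclusion_alpha).any(axis=1)
    rows = {}
    n_skipped = 0
    for pid in eff.index[include]:
        y = eff.loc[pid].dropna()
        v = var.loc[pid].reindex(y.index)
        if len(y) < 2:
            n_skipped += 1
            continue
        rows[pid] = random_effects_meta(y.to_numpy(), v.to_numpy())
    if n_skipped:
        log.info("meta_ewas: skipped %d probes present in < 2 cohorts",
                 n_skipped)
    if not rows:
        return pd.DataFrame(columns=["k", "mu", "se", "zval", "pval",
                                     "qval", "tau2", "I2", "Q"])
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "probe_id"
    out["qval"] = bh_fdr(out["pval"].to_numpy())
    return out[["k", "mu", "se", "zval", "pval", "qval", "tau2", "I2", "Q"]]


def overlap_analysis(pooled: pd.DataFrame, meta: pd.DataFrame,
                     alpha: float = 0.05) -> dict:
    """Probes nominally significant in both the pooled analysis and the
    meta-analysis, with counts for a Venn summary."""
    pooled_sig = set(pooled.index[pooled["P.Value"] < alpha])
    meta_sig = set(meta.index[meta["pval"] < alpha])
    both = pooled_sig & meta_sig
    return {
        "overlap": both,
        "n_pooled_only": len(pooled_sig - meta_sig),
        "n_meta_only": len(meta_sig - pooled_sig),
        "n_overlap": len(both),
    }
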