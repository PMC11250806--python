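"""Harmonization of merged multi-cohort data.

Cohort-of-origin acts as a batch variable: each cohort carries its own
location and scale signature.  Harmonization here is quantile
normalization followed by parametric empirical-Bayes batch adjustment
(ComBat): per probe, batch location/scale estimates are shrunk toward
batch-level priors fitted across probes, then removed.  Diagnostics use
PCA on hypervariable probes to quantify how much of the leading variance
is attributable to batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MethylationDataset, quantile_normalize

__all__ = [
    "CombatModel",
    "combat_adjust",
    "harmonize",
    "hypervariable_probes",
    "pca_batch_diagnostic",
]


@dataclass
class CombatModel:
    """Fitted parameters of the parametric EB batch adjustment."""

    batches: list[str]
    alpha: np.ndarray               # per-probe grand mean
    beta_cov: np.ndarray            # covariate coefficients (n_cov x probes)
    sigma: np.ndarray               # pooled residual SD per probe
    gamma_star: pd.DataFrame        # batch x probe EB location
    delta2_star: pd.DataFrame       # batch x probe EB scale (>0)
    hyper: pd.DataFrame             # per-batch gamma_bar, tau2, lambda, theta
    n_iterations: int
    converged: bool


def _it_sol(Z_b: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            tol: float = 1e-4, max_iter: int = 500):
    """EB posterior iteration for one batch (standardized data Z_b)."""
    n = Z_b.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    count = 0
    while count < max_iter:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((Z_b - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                     np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)))
        g_old, d_old = g_new, d_new
        count += 1
        if change < tol:
            return g_new, d_new, count, True
    return g_old, d_old, count, False


def combat_adjust(ds: MethylationDataset, batch_labels=None, covariates=None,
                  tol: float = 1e-4):
    """Parametric empirical-Bayes batch adjustment of a merged dataset.

    Steps: (1) standardize each probe using a batch + covariate least
    squares fit, (2) estimate per-batch per-probe location/scale on the
    standardized data, (3) fit normal / inverse-gamma priors across probes
    by method of moments, (4) iterate the EB posterior updates to ``tol``,
    (5) remove the shrunken batch effects and back-transform, re-adding
    covariate effects untouched.

    Parameters
    ----------
    batch_labels
        Per-sample batch labels; defaults to the dataset's ``batch`` column.
    covariates
        Optional design columns (DataFrame or 2-D array, n_samples rows)
        for biological effects to protect, e.g. case/control status.

    Returns
    -------
    (adjusted dataset, CombatModel)
    """
    if batch_labels is None:
        batch_labels = ds.samples["batch"]
    batch_labels = pd.Series(np.asarray(batch_labels), index=ds.values.index)
    batches = list(pd.unique(batch_labels))
    counts = batch_labels.value_counts()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"every batch needs >= 2 samples; too small: {bad}")

    Y = ds.values.to_numpy(dtype=float)  # n x p
    n, p = Y.shape
    B = np.column_stack([(batch_labels == b).to_numpy(float) for b in batches])

    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        # drop a covariate intercept if present: batch columns span it
        X = np.column_stack([B, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            aliased = []
            keep = list(range(B.shape[1]))
            for j in range(C.shape[1]):
                cand = np.column_stack([X[:, keep], C[:, j]])
                if np.linalg.matrix_rank(cand) == len(keep) + 1:
                    keep.append(B.shape[1] + j)
                else:
                    aliased.append(j)
            raise ValueError(
                f"covariate columns {aliased} are confounded with batch")
    else:
        C = np.zeros((n, 0))
        X = B

    if len(batches) == 1:
        model = CombatModel(batches=batches, alpha=Y.mean(axis=0),
                            beta_cov=np.zeros((C.shape[1], p)),
                            sigma=Y.std(axis=0, ddof=1),
                            gamma_star=pd.DataFrame(np.zeros((1, p)),
                                                    index=batches,
                                                    columns=ds.values.columns),
                            delta2_star=pd.DataFrame(np.ones((1, p)),
                                                     index=batches,
                                                     columns=ds.values.columns),
                            hyper=pd.DataFrame(index=batches),
                            n_iterations=0, converged=True)
        return ds.with_values(Y.copy()), model

    # --- step 1: standardize ---------------------------------------------
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_effects = coef[:len(batches)]            # batches x p
    beta_cov = coef[len(batches):]                 # n_cov x p
    frac = counts.loc[batches].to_numpy(float) / n
    alpha = frac @ batch_effects                   # weighted grand mean
    fitted = X @ coef
    sigma2 = ((Y - fitted) ** 2).sum(axis=0) / n
    sigma = np.sqrt(np.maximum(sigma2, 1e-18))
    stand_mean = alpha[None, :] + C @ beta_cov
    Z = (Y - stand_mean) / sigma[None, :]

    # --- steps 2-4: EB shrinkage ------------------------------------------
    gamma_star = np.empty((len(batches), p))
    delta2_star = np.empty((len(batches), p))
    hyper_rows = []
    total_iter, all_conv = 0, True
    for bi, b in enumerate(batches):
        sel = (batch_labels == b).to_numpy()
        Zb = Z[sel]
        nb = Zb.shape[0]
        g_hat = Zb.mean(axis=0)
        d_hat = Zb.var(axis=0, ddof=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        # inverse-gamma moments: E=beta/(a-1), V=beta^2/((a-1)^2 (a-2))
        m, v = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2.0 * v + m ** 2) / v if v > 0 else 100.0
        b_prior = (m * v + m ** 3) / v if v > 0 else m * 99.0
        g_star, d_star, its, conv = _it_sol(Zb, g_hat, d_hat, g_bar, t2,
                                            a_prior, b_prior, tol=tol)
        gamma_star[bi], delta2_star[bi] = g_star, d_star
        hyper_rows.append({"gamma_bar": g_bar, "tau2": t2,
                           "lambda": a_prior, "theta": b_prior})
        total_iter += its
        all_conv &= conv

    # --- step 5: adjust ----------------------------------------------------
    adjusted = Z.copy()
    for bi, b in enumerate(batches):
        sel = (batch_labels == b).to_numpy()
        adjusted[sel] = ((Z[sel] - gamma_star[bi][None, :])
                         / np.sqrt(delta2_star[bi])[None, :])
    adjusted = adjusted * sigma[None, :] + stand_mean

    model = CombatModel(
        batches=batches, alpha=alpha, beta_cov=beta_cov, sigma=sigma,
        gamma_star=pd.DataFrame(gamma_star, index=batches,
                                columns=ds.values.columns),
        delta2_star=pd.DataFrame(delta2_star, index=batches,
                                 columns=ds.values.columns),
        hyper=pd.DataFrame(hyper_rows, index=batches),
        n_iterations=total_iter, converged=all_conv)
    return ds.with_values(adjusted), model


def harmonize(ds: MethylationDataset, covariates=None):
    """Quantile normalization followed by ComBat (the harmonized dataset)."""
    qn = ds.with_values(quantile_normalize(ds.values.to_numpy()))
    return combat_adjust(qn, covariates=covariates)


def hypervariable_probes(beta_ds, threshold: float = 0.2) -> list[str]:
    """Probes whose cross-sample beta range (max - min) exceeds threshold."""
    if isinstance(beta_ds, MethylationDataset):
        if beta_ds.scale != "beta":
            raise ValueError("hypervariable_probes requires beta-scale input")
        mat = beta_ds.values
    else:
        mat = pd.DataFrame(beta_ds)
        if mat.to_numpy().min() < 0 or mat.to_numpy().max() > 1:
            raise ValueError("hypervariable_probes requires beta-scale input")
    rng_ = mat.max(axis=0) - mat.min(axis=0)
    return list(mat.columns[(rng_ > threshold).to_numpy()])


def pca_batch_diagnostic(ds: MethylationDataset, labels=None,
                         threshold: float = 0.2) -> dict:
    """First two PCs of the hypervariable-probe submatrix, with the share
    of PC1/PC2 variance explained by a categorical label (one-way R^2).

    A large batch R^2 on PC1 before adjustment and a small one after is
    the expected signature of successful harmonization.
    """
    if ds.n_samples < 3:
        raise ValueError("need at least 3 samples for the PCA diagnostic")
    if labels is None:
        labels = ds.samples["batch"]
    labels = pd.Series(np.asarray(labels), index=ds.values.index)

    beta = ds.to_beta()
    hv = hypervariable_probes(beta, threshold=threshold)
    if len(hv) < 2:
        hv = list(beta.values.columns)  # fall back to all probes
    if len(hv) < 2:
        raise ValueError("fewer than 2 probes available for PCA")
    X = ds.values[hv].to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    # thin SVD; components scaled to scores
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :2] * S[:2]

    def anova_r2(y: np.ndarray) -> float:
        groups = [y[(labels == g).to_numpy()] for g in pd.unique(labels)]
        grand = y.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_total = ((y - grand) ** 2).sum()
        return float(ss_between / ss_total) if ss_total > 0 else 0.0

    centroids = {str(g): scores[(labels == g).to_numpy()].mean(axis=0).tolist()
                 for g in pd.unique(labels)}
    total_var = (X ** 2).sum()
    return {
        "n_hypervariable": len(hv),
        "explained_fraction": [float(S[0] ** 2 / total_var),
                               float(S[1] ** 2 / total_var)] if total_var > 0 else [0.0, 0.0],
        "scores": scores,
        "r2_pc1": anova_r2(scores[:, 0]),
        "r2_pc2": anova_r2(scores[:, 1]),
        "centroids": centroids,
    }
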