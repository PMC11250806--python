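"""Feature-selection strategies for methylation classifiers.

Seven strategies with a uniform result type: differential-methylation
top-k (the limma-style route), the biased pre-selected panel (top-k of a
pooled DM table restricted to direction-consistent probes, fitted on ALL
samples — the construction whose optimism the evaluation module
measures), variance top-fraction, ANOVA F, L1-penalized linear SVC and
logistic regression, and ExtraTrees impurity importance.  Every result
records the exact sample ids it was fitted on so the evaluation layer can
audit information leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .core import MethylationDataset
from .ewas import run_ewas

__all__ = [
    "SelectionResult",
    "select_dm_top",
    "select_biased_panel",
    "select_variance_top",
    "select_anova_f",
    "select_l1_model",
    "select_tree_importance",
]


@dataclass
class SelectionResult:
    """Probes chosen by one strategy, with leakage-audit provenance."""

    strategy: str
    probe_ids: list[str]          # ordered by score (best first)
    scores: np.ndarray
    fitted_on: frozenset = field(default_factory=frozenset)
    biased: bool = False

    def __len__(self) -> int:
        return len(self.probe_ids)


def _check_two_classes(labels) -> np.ndarray:
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def _as_matrix(data):
    if isinstance(data, MethylationDataset):
        return (data.values.to_numpy(dtype=float),
                list(data.values.columns), frozenset(data.sample_ids))
    df = pd.DataFrame(data)
    return df.to_numpy(dtype=float), list(df.columns), frozenset(df.index)


def select_dm_top(train: MethylationDataset, k: int = 200) -> SelectionResult:
    """Top-k probes by moderated-t p-value from an EWAS on the training
    samples only (cohort mode: age + sex covariates, no study factor)."""
    _check_two_classes(train.status_codes)
    if k > train.n_probes:
        raise ValueError(f"k={k} exceeds probe count {train.n_probes}")
    table = run_ewas(train, include_study_factor=False, with_agreement=False)
    order = np.lexsort((np.arange(len(table)), table["P.Value"].to_numpy()))
    top = order[:k]
    return SelectionResult(
        strategy="dm_top",
        probe_ids=[table.index[i] for i in top],
        scores=table["P.Value"].to_numpy()[top],
        fitted_on=frozenset(train.sample_ids))


def select_biased_panel(pooled_dm: pd.DataFrame, all_sample_ids,
                        agreement_threshold: float = 1.0,
                        k: int = 200) -> SelectionResult:
    """The pre-selected panel: top-k pooled-DM probes whose directional
    agreement meets the threshold.  Fitted on every sample, so any CV that
    reuses it is positively biased by construction."""
    if "agreement" not in pooled_dm.columns:
        raise ValueError("pooled DM table must carry an agreement column")
    consistent = pooled_dm[pooled_dm["agreement"] >= agreement_threshold]
    if len(consistent) == 0:
        warnings.warn("no probes meet the agreement threshold; empty panel",
                      stacklevel=2)
    if len(consistent) < k:
        warnings.warn(
            f"only {len(consistent)} direction-consistent probes available "
            f"(< k={k}); returning all of them", stacklevel=2)
    ranked = consistent.sort_values("P.Value", kind="stable").head(k)
    return SelectionResult(
        strategy="biased_panel",
        probe_ids=list(ranked.index),
        scores=ranked["P.Value"].to_numpy(),
        fitted_on=frozenset(all_sample_ids),
        biased=True)


def select_variance_top(matrix, fraction: float) -> SelectionResult:
    """Top probes by cross-sample variance; retains ceil(fraction * p).

    The ceiling rule reproduces the canonical counts for an array-scale
    input: 304,765 probes yield 15,239 / 3,048 / 305 features at
    fractions 0.05 / 0.01 / 0.001.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    X, probe_ids, fitted_on = _as_matrix(matrix)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    var = X.var(axis=0, ddof=1)
    n_keep = int(np.ceil(fraction * X.shape[1]))
    order = np.lexsort((np.arange(len(var)), -var))  # ties by probe order
    top = order[:n_keep]
    return SelectionResult(strategy=f"variance_top_{fraction}",
                           probe_ids=[probe_ids[i] for i in top],
                           scores=var[top], fitted_on=fitted_on)


def select_anova_f(matrix, labels, k: int = 200) -> SelectionResult:
    """Top-k probes by one-way ANOVA F between the two classes."""
    y = _check_two_classes(labels)
    X, probe_ids, fitted_on = _as_matrix(matrix)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds probe count {X.shape[1]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant probes yield F = nan
        F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0)
    order = np.lexsort((np.arange(len(F)), -F))
    top = order[:k]
    return SelectionResult(strategy="anova_f",
                           probe_ids=[probe_ids[i] for i in top],
                           scores=F[top], fitted_on=fitted_on)


def select_l1_model(matrix, labels, model: str = "logistic", k: int = 200,
                    max_iter: int = 5000, C: float = 1.0,
                    seed: int = 0) -> SelectionResult:
    """Top-k probes by |coefficient| of an L1-penalized linear model.

    When the penalty leaves fewer than k nonzero coefficients the panel is
    padded with the largest-magnitude remaining ones (which preserves the
    requested size at the cost of including zero-weight probes).
    """
    y = _check_two_classes(labels)
    X, probe_ids, fitted_on = _as_matrix(matrix)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds probe count {X.shape[1]}")
    if model == "linear_svc":
        est = LinearSVC(penalty="l1", dual=False, C=C, max_iter=max_iter,
                        random_state=seed)
    elif model == "logistic":
        est = LogisticRegression(penalty="l1", solver="liblinear", C=C,
                                 max_iter=max_iter, random_state=seed)
    else:
        raise ValueError("model must be 'linear_svc' or 'logistic'")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        est.fit(X, y)
    for w in caught:
        if "onverge" in str(w.message):
            warnings.warn(f"L1 selector did not converge in {max_iter} "
                          "iterations; using current coefficients",
                          stacklevel=2)
    coefs = np.abs(np.ravel(est.coef_))
    n_nonzero = int((coefs > 0).sum())
    if n_nonzero < k:
        warnings.warn(
            f"only {n_nonzero} nonzero L1 coefficients; padding to k={k} "
            "with largest-magnitude remainder", stacklevel=2)
    order = np.lexsort((np.arange(len(coefs)), -coefs))
    top = order[:k]
    return SelectionResult(strategy=f"l1_{model}",
                           probe_ids=[probe_ids[i] for i in top],
                           scores=coefs[top], fitted_on=fitted_on)


def select_tree_importance(matrix, labels, k: int = 200,
                           seed: int = 0, n_estimators: int = 100
                           ) -> SelectionResult:
    """Top-k probes by ExtraTrees impurity importance (seeded)."""
    y = _check_two_classes(labels)
    X, probe_ids, fitted_on = _as_matrix(matrix)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds probe count {X.shape[1]}")
    est = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed)
    est.fit(X, y)
    imp = est.feature_importances_
    order = np.lexsort((np.arange(len(imp)), -imp))
    top = order[:k]
    return SelectionResult(strategy="extratrees",
                           probe_ids=[probe_ids[i] for i in top],
                           scores=imp[top], fitted_on=fitted_on)
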