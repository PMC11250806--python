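"""Leakage-aware classifier evaluation.

The protocol mirrors a multi-cohort methylation study: repeated
stratified cross-validation with feature selection re-run inside every
training fold (unbiased), the same CV with a panel pre-selected on all
samples (biased — the optimism this module is built to measure), and
batch-based hold-out testing in which entire cohort batches are reserved
for the test set so no cohort-level preprocessing leaks across the
boundary.  Two headline experiments quantify the methodological effects:
the selection-bias AUC gap on null data, and the batch-leakage contrast
between batch-level and harmonized preparations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold

from .core import MethylationDataset, merge_batches
from .harmonize import harmonize
from .models import ModelSpec, train
from .selection import (SelectionResult, select_anova_f, select_dm_top,
                        select_l1_model, select_tree_importance,
                        select_variance_top)
from .simulate import SimulationConfig, generate_study

__all__ = [
    "EvalProtocol",
    "SelectorSpec",
    "EvalResult",
    "make_cv_splits",
    "roc_auc",
    "evaluate_unbiased",
    "evaluate_biased",
    "evaluate_holdout",
    "bias_gap_experiment",
    "leakage_contrast_experiment",
]


@dataclass
class EvalProtocol:
    """Cross-validation and hold-out layout."""

    n_repeats: int = 10
    n_folds: int = 3
    stratified: bool = True
    seed: int = 0
    cv_batches: frozenset = field(default_factory=frozenset)
    holdout_batches: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.cv_batches & self.holdout_batches:
            raise ValueError("cv_batches and holdout_batches must be disjoint")


@dataclass
class SelectorSpec:
    """A within-fold feature-selection strategy (unbiased when applied to
    training samples only)."""

    kind: str  # dm_top | variance | anova_f | l1_logistic | l1_svc | extratrees
    k: int = 200
    fraction: float = 0.05
    seed: int = 0
    kwargs: dict = field(default_factory=dict)

    def apply(self, train_ds: MethylationDataset) -> SelectionResult:
        y = train_ds.status_codes
        if self.kind == "dm_top":
            return select_dm_top(train_ds, k=self.k)
        if self.kind == "variance":
            return select_variance_top(train_ds, fraction=self.fraction)
        if self.kind == "anova_f":
            return select_anova_f(train_ds, y, k=self.k)
        if self.kind == "l1_logistic":
            return select_l1_model(train_ds, y, model="logistic", k=self.k,
                                   seed=self.seed, **self.kwargs)
        if self.kind == "l1_svc":
            return select_l1_model(train_ds, y, model="linear_svc", k=self.k,
                                   seed=self.seed, **self.kwargs)
        if self.kind == "extratrees":
            return select_tree_importance(train_ds, y, k=self.k,
                                          seed=self.seed, **self.kwargs)
        raise ValueError(f"unknown selector kind {self.kind!r}")


@dataclass
class EvalResult:
    """Per-fold metrics and their aggregates for one evaluation cell."""

    folds: pd.DataFrame  # columns: auc, accuracy, sensitivity, specificity
    model_manifest: str
    selection_strategy: str
    preparation: str = "batch_level"
    biased: bool = False

    @property
    def mean_auc(self) -> float:
        return float(self.folds["auc"].mean())

    def summary(self) -> dict:
        agg = {f"{c}_mean": float(self.folds[c].mean())
               for c in self.folds.columns}
        agg.update({f"{c}_sd": float(self.folds[c].std(ddof=1))
                    for c in self.folds.columns})
        agg["n_folds"] = len(self.folds)
        agg["biased"] = self.biased
        agg["preparation"] = self.preparation
        return agg


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random case outscores random control), ties 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _metrics(scores: np.ndarray, y: np.ndarray) -> dict:
    pred = (scores >= 0.5).astype(int)
    pos, neg = y == 1, y == 0
    return {
        "auc": roc_auc(scores, y),
        "accuracy": float((pred == y).mean()),
        "sensitivity": float(pred[pos].mean()) if pos.any() else np.nan,
        "specificity": float(1 - pred[neg].mean()) if neg.any() else np.nan,
    }


def make_cv_splits(ds: MethylationDataset, protocol: EvalProtocol):
    """n_repeats x n_folds (train ids, validation ids) pairs; each repeat's
    validation sets partition the samples; stratified by class when
    flagged; fully determined by the protocol seed."""
    y = ds.status_codes
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    ids = np.array(ds.sample_ids)
    cls = RepeatedStratifiedKFold if protocol.stratified else RepeatedKFold
    splitter = cls(n_splits=protocol.n_folds, n_repeats=protocol.n_repeats,
                   random_state=protocol.seed)
    splits = []
    for tr, va in splitter.split(np.zeros(len(y)), y):
        if protocol.stratified is False and (len(np.unique(y[tr])) < 2
                                             or len(np.unique(y[va])) < 2):
            raise ValueError("a fold lost a class; use stratified=True")
        splits.append((list(ids[tr]), list(ids[va])))
    return splits


def _run_cv(ds, model_spec, protocol, select_fn, strategy_name, biased,
            preparation="batch_level"):
    splits = make_cv_splits(ds, protocol)
    rows = []
    for fold_i, (train_ids, val_ids) in enumerate(splits):
        train_ds = ds.subset_samples(train_ids)
        sel = select_fn(train_ds)
        if not biased and sel.fitted_on & set(val_ids):
            raise RuntimeError(
                "leakage audit failed: selector was fitted on validation "
                "samples in an unbiased evaluation")
        probes = sel.probe_ids
        Xtr = train_ds.values[probes].to_numpy(float)
        ytr = train_ds.status_codes
        val_ds = ds.subset_samples(val_ids)
        Xva = val_ds.values[probes].to_numpy(float)
        yva = val_ds.status_codes
        fitted = train(replace(model_spec, seed=model_spec.seed + fold_i),
                       Xtr, ytr)
        rows.append(_metrics(fitted.score(Xva), yva))
    return EvalResult(folds=pd.DataFrame(rows),
                      model_manifest=model_spec.manifest(),
                      selection_strategy=strategy_name, biased=biased,
                      preparation=preparation)


def evaluate_unbiased(ds: MethylationDataset, model_spec: ModelSpec,
                      selector: SelectorSpec, protocol: EvalProtocol,
                      preparation: str = "batch_level") -> EvalResult:
    """Repeated CV with the selector re-fit inside every training fold.

    A hard leakage audit rejects any selection whose provenance overlaps
    the fold's validation samples.
    """
    return _run_cv(ds, model_spec, protocol, selector.apply, selector.kind,
                   biased=False, preparation=preparation)


def evaluate_biased(ds: MethylationDataset, model_spec: ModelSpec,
                    panel: SelectionResult, protocol: EvalProtocol,
                    preparation: str = "batch_level") -> EvalResult:
    """Repeated CV with a fixed pre-selected panel (fitted on all samples).

    Identical bookkeeping to :func:`evaluate_unbiased`; the result is
    tagged biased because the panel has seen the validation samples.
    """
    missing = set(panel.probe_ids) - set(ds.probe_ids)
    if missing:
        raise ValueError(f"panel probes absent from dataset: {sorted(missing)[:5]}")
    return _run_cv(ds, model_spec, protocol, lambda _train: panel,
                   panel.strategy, biased=True, preparation=preparation)


def evaluate_holdout(train_ds: MethylationDataset, test_ds: MethylationDataset,
                     model_spec: ModelSpec, selector_or_panel,
                     n_training_repeats: int = 5,
                     preparation: str = "batch_level") -> EvalResult:
    """Train on whole cohort batches, test on disjoint held-out batches.

    Feature selection (if a :class:`SelectorSpec`) runs on the full
    training set; training is repeated with ``n_training_repeats`` seeds
    and metrics are reported per repeat.
    """
    tr_batches = set(train_ds.samples["batch"])
    te_batches = set(test_ds.samples["batch"])
    if tr_batches & te_batches:
        raise ValueError(f"batch overlap between train and test: "
                         f"{sorted(tr_batches & te_batches)}")
    if isinstance(selector_or_panel, SelectorSpec):
        sel = selector_or_panel.apply(train_ds)
        biased = False
    else:
        sel = selector_or_panel
        biased = bool(getattr(sel, "biased", False))
    probes = [p for p in sel.probe_ids if p in train_ds.values.columns]
    Xtr = train_ds.values[probes].to_numpy(float)
    ytr = train_ds.status_codes
    Xte = test_ds.values[probes].to_numpy(float)
    yte = test_ds.status_codes
    rows = []
    for rep in range(n_training_repeats):
        fitted = train(replace(model_spec, seed=model_spec.seed + rep),
                       Xtr, ytr)
        rows.append(_metrics(fitted.score(Xte), yte))
    return EvalResult(folds=pd.DataFrame(rows),
                      model_manifest=model_spec.manifest(),
                      selection_strategy=sel.strategy, biased=biased,
                      preparation=preparation)


def _sign_flip_pvalue(diffs: np.ndarray, rng: np.random.Generator,
                      n_perm: int = 2000) -> float:
    """Paired sign-flip permutation test for mean(diffs) > 0."""
    observed = diffs.mean()
    flips = rng.choice([-1.0, 1.0], size=(n_perm, len(diffs)))
    null = (flips * diffs).mean(axis=1)
    return float((np.sum(null >= observed) + 1) / (n_perm + 1))


def bias_gap_experiment(sim_config: SimulationConfig,
                        model_specs: list[ModelSpec],
                        protocol: EvalProtocol,
                        selector: SelectorSpec | None = None,
                        panel_k: int = 200) -> pd.DataFrame:
    """Biased vs unbiased CV AUC for every model on one simulated study.

    The biased panel is the top-``panel_k`` probes by whole-data
    differential methylation; the unbiased arm repeats the same selection
    inside every training fold.  Reports the per-model AUC gap with a
    paired sign-flip permutation p-value.
    """
    datasets, _truth = generate_study(sim_config)
    ds = merge_batches(datasets)
    selector = selector or SelectorSpec("dm_top", k=panel_k)
    panel = select_dm_top(ds, k=panel_k)  # fitted on ALL samples
    rng = np.random.default_rng(protocol.seed)
    rows = []
    for spec in model_specs:
        unbiased = evaluate_unbiased(ds, spec, selector, protocol)
        biased = evaluate_biased(ds, spec, panel, protocol)
        diffs = (biased.folds["auc"].to_numpy()
                 - unbiased.folds["auc"].to_numpy())
        rows.append({
            "family": spec.family,
            "auc_unbiased": unbiased.mean_auc,
            "auc_biased": biased.mean_auc,
            "gap": float(diffs.mean()),
            "p_perm": _sign_flip_pvalue(diffs, rng),
        })
    return pd.DataFrame(rows)


def _split_batches(datasets, holdout_batches):
    tr = [d for d in datasets if d.samples["batch"].iloc[0] not in holdout_batches]
    te = [d for d in datasets if d.samples["batch"].iloc[0] in holdout_batches]
    return merge_batches(tr), merge_batches(te)


def leakage_contrast_experiment(sim_config: SimulationConfig,
                                model_spec: ModelSpec,
                                holdout_batches: set[str] | None = None,
                                selector: SelectorSpec | None = None,
                                n_training_repeats: int = 3) -> dict:
    """Hold-out AUC on batch-level vs harmonized preparations.

    Harmonization (quantile normalization + ComBat) is applied to the
    merged data INCLUDING the held-out batches, exactly the whole-dataset
    preprocessing whose leakage consequences are under study.  Under a
    batch-confounded design the batch-level preparation rides the batch
    signal to inflated test AUC; harmonization removes it.
    """
    datasets, _truth = generate_study(sim_config)
    if holdout_batches is None:
        holdout_batches = {f"batch{b}" for b in range(5, sim_config.n_batches)}
    selector = selector or SelectorSpec("dm_top", k=200)

    train_raw, test_raw = _split_batches(datasets, holdout_batches)
    res_batch = evaluate_holdout(train_raw, test_raw, model_spec, selector,
                                 n_training_repeats=n_training_repeats,
                                 preparation="batch_level")

    merged = merge_batches(datasets)
    harmonized, _model = harmonize(merged)
    is_test = harmonized.samples["batch"].isin(holdout_batches).to_numpy()
    train_h = harmonized.subset_samples(np.array(harmonized.sample_ids)[~is_test])
    test_h = harmonized.subset_samples(np.array(harmonized.sample_ids)[is_test])
    res_harm = evaluate_holdout(train_h, test_h, model_spec, selector,
                                n_training_repeats=n_training_repeats,
                                preparation="harmonized")
    return {
        "auc_batch_level": res_batch.mean_auc,
        "auc_harmonized": res_harm.mean_auc,
        "difference": res_batch.mean_auc - res_harm.mean_auc,
        "batch_level": res_batch,
        "harmonized": res_harm,
    }
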