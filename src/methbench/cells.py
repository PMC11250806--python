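"""Reference-based cell-composition estimation and adjustment.

Whole blood is a mixture of leukocyte subtypes with distinct methylation
profiles, so case/control differences in cell composition masquerade as
CpG-level effects.  Two standard remedies are implemented: Houseman-style
constrained projection of each sample's beta profile onto a cell-type
reference panel, and a per-probe regression adjustment in which the
residuals after regressing out cell proportions are added back to the
probe mean (preserving the probe's location while removing the
composition-explained variance).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import MethylationDataset
from .simulate import CellReferencePanel

__all__ = [
    "CellProportionEstimate",
    "estimate_cell_proportions",
    "estimate_cell_proportions_dataset",
    "adjust_for_cell_composition",
]


@dataclass
class CellProportionEstimate:
    """Estimated mixing proportions for one sample."""

    proportions: pd.Series  # indexed by cell type, >= 0, sums to 1
    residual_norm: float


def _check_panel_rank(R: np.ndarray, celltypes: list[str]) -> None:
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[0]:
        # name the most collinear pair to help the caller fix the panel
        c = np.corrcoef(R)
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(c)), c.shape)
        raise ValueError(
            f"reference panel is rank-deficient (rank {rank} < "
            f"{R.shape[0]}); most collinear cell types: "
            f"{celltypes[i]} ~ {celltypes[j]}")


def estimate_cell_proportions(sample_beta, panel: CellReferencePanel,
                              probes: list[str] | None = None
                              ) -> CellProportionEstimate:
    """Project one beta profile onto the reference panel.

    Solves min ||b - R^T w||^2 subject to w >= 0 and sum(w) = 1 over the
    panel's discriminating probes.  The simplex constraint is imposed by
    non-negative least squares with a heavily weighted sum-to-one row
    followed by exact renormalization.
    """
    use = probes if probes is not None else panel.discriminating_probes
    if len(use) < len(panel.celltypes):
        raise ValueError("need at least n_celltypes shared discriminating probes")
    b = pd.Series(sample_beta)
    b = b.loc[use].to_numpy(dtype=float)
    R = panel.reference_beta[use].to_numpy(dtype=float)  # K x P
    _check_panel_rank(R, panel.celltypes)
    # append the equality constraint as a strongly weighted row
    lam = 1000.0
    A = np.vstack([R.T, lam * np.ones(R.shape[0])])
    y = np.concatenate([b, [lam]])
    w, _ = nnls(A, y)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate projection: all-zero weights")
    w = w / total
    resid = float(np.linalg.norm(b - R.T @ w))
    return CellProportionEstimate(
        proportions=pd.Series(w, index=panel.celltypes),
        residual_norm=resid)


def estimate_cell_proportions_dataset(ds: MethylationDataset,
                                      panel: CellReferencePanel
                                      ) -> pd.DataFrame:
    """Houseman projection for every sample; returns sample x celltype."""
    beta = ds.to_beta().values
    shared = [p for p in panel.discriminating_probes if p in beta.columns]
    rows = {}
    for sid in beta.index:
        est = estimate_cell_proportions(beta.loc[sid], panel, probes=shared)
        rows[sid] = est.proportions
    return pd.DataFrame.from_dict(rows, orient="index")[panel.celltypes]


def adjust_for_cell_composition(ds: MethylationDataset,
                                proportions: pd.DataFrame
                                ) -> MethylationDataset:
    """Residual+mean adjustment: remove composition-explained variance.

    Per probe, methylation is regressed on the cell proportions (intercept
    plus K-1 proportion columns; the last cell type is dropped as the
    reference because proportions sum to one) and the residuals are added
    back to the probe mean.  The adjustment is exactly mean-preserving and
    idempotent.
    """
    if list(proportions.index) != list(ds.values.index):
        proportions = proportions.loc[ds.values.index]
    K = proportions.shape[1]
    n = ds.n_samples
    if n < K + 2:
        raise ValueError("need at least n_celltypes + 2 samples")
    P = proportions.to_numpy(dtype=float)[:, :-1]  # drop reference column
    X = np.column_stack([np.ones(n), P])
    # guard residual collinearity among the remaining columns
    if np.linalg.matrix_rank(X) < X.shape[1]:
        keep = [0]
        for j in range(1, X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
        X = X[:, keep]
    Y = ds.values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    adjusted = resid + Y.mean(axis=0, keepdims=True)
    out = ds.with_values(adjusted)
    if ds.scale == "beta":
        # residual+mean can stray outside [0,1] on the beta scale
        out = ds.with_values(np.clip(adjusted, 0.0, 1.0))
    return out
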