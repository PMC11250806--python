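"""Core containers and matrix operations for methylation array data.

The in-memory contract throughout the package is a samples x probes matrix
(on-disk files use the GEO series-matrix orientation, probes as rows; the
readers in :mod:`methbench.io` transpose).  Methylation is carried either as
beta-values (bounded methylation fractions in [0, 1]) or M-values (logit2 of
beta, approximately Gaussian and preferred for linear modelling).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "beta_to_m",
    "m_to_beta",
    "quantile_normalize",
    "filter_probes",
    "merge_batches",
]

#: default clipping for saturated beta-values before the logit2 transform
DEFAULT_EPSILON = 1e-6

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class MethylationDataset:
    """A sample x probe methylation matrix with sample and probe metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per probe id.
    scale
        ``"beta"`` or ``"M"``.
    samples
        Per-sample metadata indexed by sample id.  Expected columns:
        ``status`` (``"case"``/``"control"``), ``age`` (years), ``sex``
        (``"F"``/``"M"``), ``batch``; optionally one ``prop_<celltype>``
        column per blood cell type.
    probes
        Per-probe annotation indexed by probe id with columns ``chrom`` and
        ``pos`` (1-based, Illumina-manifest convention).
    """

    values: pd.DataFrame
    scale: str
    samples: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValueError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if not self.values.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("probe ids must be unique")
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values rows and sample sheet must align")
        if not self.values.columns.equals(self.probes.index):
            raise ValueError("values columns and probe annotation must align")
        if self.scale == "beta":
            v = self.values.to_numpy()
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError("beta-scale values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_m(self, epsilon: float = DEFAULT_EPSILON) -> "MethylationDataset":
        """Return the dataset on the M scale (identity if already M)."""
        if self.scale == "M":
            return self
        m = beta_to_m(self.values.to_numpy(), epsilon=epsilon)
        return replace(self, values=pd.DataFrame(m, index=self.values.index,
                                                 columns=self.values.columns),
                       scale="M")

    def to_beta(self) -> "MethylationDataset":
        """Return the dataset on the beta scale (identity if already beta)."""
        if self.scale == "beta":
            return self
        b = m_to_beta(self.values.to_numpy())
        return replace(self, values=pd.DataFrame(b, index=self.values.index,
                                                 columns=self.values.columns),
                       scale="beta")

    def with_values(self, new_values: np.ndarray | pd.DataFrame,
                    scale: str | None = None) -> "MethylationDataset":
        """Return a copy with the matrix replaced (metadata shared)."""
        if isinstance(new_values, np.ndarray):
            new_values = pd.DataFrame(new_values, index=self.values.index,
                                      columns=self.values.columns)
        return replace(self, values=new_values,
                       scale=self.scale if scale is None else scale)

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        ids = list(sample_ids)
        return replace(self, values=self.values.loc[ids],
                       samples=self.samples.loc[ids])

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        ids = list(probe_ids)
        return replace(self, values=self.values[ids],
                       probes=self.probes.loc[ids])

    @property
    def status_codes(self) -> np.ndarray:
        """Binary labels: 1 = case, 0 = control."""
        return (self.samples["status"].to_numpy() == "case").astype(int)


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """logit2 transform: M = log2(beta / (1 - beta)).

    Saturated betas are clipped to [epsilon, 1 - epsilon] so the transform
    stays finite at 0 and 1.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    b = np.asarray(beta, dtype=float)
    if np.nanmin(b) < 0 or np.nanmax(b) > 1:
        raise ValueError("beta-values must lie in [0, 1]")
    b = np.clip(b, epsilon, 1.0 - epsilon)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (2^M + 1), strictly in (0, 1)."""
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("M-values must be finite")
    # expit formulation avoids overflow for large |M|
    from scipy.special import expit

    out = expit(arr * np.log(2.0))
    return out if out.ndim else float(out)


def quantile_normalize(matrix) -> np.ndarray:
    """Force every sample (row) to share the mean empirical distribution.

    Each sample's sorted vector is replaced by the cross-sample mean of
    sorted vectors; ties within a sample receive the mean of the quantile
    values they span.

    Parameters
    ----------
    matrix
        samples x probes array-like, no missing values.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if np.isnan(x).any():
        raise ValueError(
            "missing values present: impute or filter probes before "
            "quantile normalization"
        )
    n, p = x.shape
    mean_sorted = np.sort(x, axis=1).mean(axis=0)
    # cumulative means let a tie block average its spanned quantiles in O(1)
    csum = np.concatenate([[0.0], np.cumsum(mean_sorted)])
    out = np.empty_like(x)
    for i in range(n):
        order = np.argsort(x[i], kind="stable")
        sorted_vals = x[i][order]
        assigned = np.empty(p)
        j = 0
        while j < p:
            k = j
            while k + 1 < p and sorted_vals[k + 1] == sorted_vals[j]:
                k += 1
            assigned[j:k + 1] = (csum[k + 1] - csum[j]) / (k + 1 - j)
            j = k + 1
        out[i][order] = assigned
    return out


def filter_probes(ds: MethylationDataset, exclusion_list=(),
                  drop_sex_chrom: bool = True) -> MethylationDataset:
    """Drop user-listed probes (SNP-related, cross-reactive, ...) and,
    optionally, all chrX/chrY probes."""
    excl = set(exclusion_list)
    keep = []
    n_listed = n_sex = 0
    for pid, row in ds.probes.iterrows():
        if pid in excl:
            n_listed += 1
        elif drop_sex_chrom and row["chrom"] in SEX_CHROMS:
            n_sex += 1
        else:
            keep.append(pid)
    if not keep:
        warnings.warn("probe filtering removed every probe", stacklevel=2)
    if n_listed or n_sex:
        logging.getLogger(__name__).info(
            "filter_probes: removed %d listed and %d sex-chromosome probes",
            n_listed, n_sex)
    return ds.subset_probes(keep)


def _sorted_probe_order(probes: pd.DataFrame) -> list[str]:
    def chrom_key(c: str):
        c = c.removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    keys = [(chrom_key(row["chrom"]), int(row["pos"]), pid)
            for pid, row in probes.iterrows()]
    return [pid for _, _, pid in sorted(keys)]


def merge_batches(datasets: list[MethylationDataset]) -> MethylationDataset:
    """Concatenate cohort batches over the probes shared by all of them.

    The probe set is the intersection across batches, ordered by genomic
    position (chrom, pos) so every sample carries its features in the same
    order; samples are stacked and keep their batch labels.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    scales = {d.scale for d in datasets}
    if len(scales) > 1:
        raise ValueError(f"cannot merge mixed scales: {sorted(scales)}")
    common = set(datasets[0].probe_ids)
    for d in datasets[1:]:
        common &= set(d.probe_ids)
    if not common:
        raise ValueError("probe intersection across batches is empty")
    order = [p for p in _sorted_probe_order(datasets[0].probes.loc[list(common)])]
    all_ids = [sid for d in datasets for sid in d.sample_ids]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("sample ids must be globally unique across batches")
    values = pd.concat([d.values[order] for d in datasets], axis=0)
    samples = pd.concat([d.samples for d in datasets], axis=0)
    return MethylationDataset(values=values, scale=datasets[0].scale,
                              samples=samples,
                              probes=datasets[0].probes.loc[order])
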