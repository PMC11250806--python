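"""Plain-text readers and writers.

On-disk layout follows the GEO series-matrix convention: the methylation
matrix is a TSV with probes as rows and samples as columns (first column
``probe_id``); the sample sheet is a CSV with columns sample_id, status,
age, sex, batch; the probe annotation is a TSV with probe_id, chrom, pos
(1-based, Illumina-manifest convention).  All readers and writers are
gzip-transparent (pass a ``.gz`` path).  In memory the matrix is
transposed to samples x probes.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import MethylationDataset
from .simulate import GroundTruth

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_truth",
    "read_truth",
    "write_proportions",
    "read_proportions",
]

_MATRIX = "matrix.tsv"
_SAMPLES = "samples.csv"
_PROBES = "probes.tsv"


def write_dataset(ds: MethylationDataset, out_dir, gzip: bool = False) -> Path:
    """Write matrix TSV, sample sheet CSV and probe annotation TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip else ""
    ds.values.T.rename_axis("probe_id").to_csv(
        out / (_MATRIX + suffix), sep="\t")
    ds.samples.rename_axis("sample_id").to_csv(out / (_SAMPLES + suffix))
    ds.probes.rename_axis("probe_id").to_csv(
        out / (_PROBES + suffix), sep="\t")
    (out / "scale.txt").write_text(ds.scale + "\n")
    return out


def read_dataset(in_dir, scale: str | None = None) -> MethylationDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    src = Path(in_dir)

    def find(name):
        p = src / name
        return p if p.exists() else src / (name + ".gz")

    matrix = pd.read_csv(find(_MATRIX), sep="\t", index_col="probe_id")
    samples = pd.read_csv(find(_SAMPLES), index_col="sample_id")
    probes = pd.read_csv(find(_PROBES), sep="\t", index_col="probe_id")
    if scale is None:
        scale_file = src / "scale.txt"
        scale = scale_file.read_text().strip() if scale_file.exists() else "M"
    return MethylationDataset(values=matrix.T, scale=scale,
                              samples=samples.loc[matrix.columns],
                              probes=probes.loc[matrix.index])


def write_truth(truth: GroundTruth, path) -> Path:
    """Ground truth as JSON (reference panel stored alongside as TSV)."""
    path = Path(path)
    payload = {
        "signal_probe_ids": sorted(truth.signal_probe_ids),
        "per_probe_effect": truth.per_probe_effect,
        "batch_shifts": {b: list(v) for b, v in truth.batch_shifts.items()},
        "cell_proportions": {sid: truth.cell_proportions.loc[sid].tolist()
                             for sid in truth.cell_proportions.index},
        "celltypes": list(truth.cell_proportions.columns),
    }
    path.write_text(json.dumps(payload, indent=1))
    panel_path = path.with_suffix(".panel.tsv")
    truth.cell_reference.reference_beta.rename_axis("celltype").to_csv(
        panel_path, sep="\t")
    return path


def read_truth(path) -> dict:
    """Ground truth back as a plain dict (panel not reloaded)."""
    return json.loads(Path(path).read_text())


def write_proportions(props: pd.DataFrame, path) -> Path:
    path = Path(path)
    props.rename_axis("sample_id").to_csv(path)
    return path


def read_proportions(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")
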