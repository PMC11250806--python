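"""Synthetic multi-batch methylation studies with known ground truth.

The generator emulates the structure of a pooled case/control blood
methylation study assembled from several cohort batches: per-batch mean and
variance shifts, class imbalance that differs between batches (pooled
roughly 58% cases), blood cell-type mixtures behind every sample, age/sex
covariates, and a set of planted case-control effect probes.  Everything is
seeded and the planted parameters are returned as a :class:`GroundTruth`
object so downstream stages can be scored against a known answer.

Values are simulated on the M scale (where Gaussian noise is a reasonable
model and linear modelling assumptions hold); conversion back to beta always
lands in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MethylationDataset, beta_to_m

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CellReferencePanel",
    "generate_reference_panel",
    "generate_batch",
    "generate_study",
]

DEFAULT_CELLTYPES = ("CD8T", "CD4T", "NK", "B", "Mono", "Gran")

# typical whole-blood composition; Dirichlet concentrations are these
# proportions scaled by a precision of 30
_BLOOD_PROPORTIONS = {"CD8T": 0.08, "CD4T": 0.15, "NK": 0.05,
                      "B": 0.05, "Mono": 0.07, "Gran": 0.60}

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


def _default_case_fractions() -> list[float]:
    # varies across batches, pooled fraction ~0.58 cases; some batches
    # control-heavy to mirror the inconsistent imbalance of real cohorts
    return [0.75, 0.35, 0.70, 0.50, 0.85, 0.25, 0.65, 0.60]


def _default_samples_per_batch() -> list[int]:
    return [243] * 8  # ~1942 pooled samples


@dataclass
class SimulationConfig:
    """Parameters of a simulated multi-batch case/control study.

    Defaults describe an eight-batch study of ~1942 samples with batch
    location/scale heterogeneity and a modest planted effect at 100 of
    5000 probes.  ``effect_size_m`` is the case-minus-control difference in
    M-units at signal probes.  ``confound_cells_with_status`` couples the
    Dirichlet concentration of cell mixtures to case status (off by
    default) so the cell-adjustment stage can be stress-tested;
    ``confound_batch_with_status`` makes the batch mean shift a
    deterministic function of the batch's case fraction, creating the
    batch-leakage scenario.
    """

    n_batches: int = 8
    samples_per_batch: list[int] = field(default_factory=_default_samples_per_batch)
    case_fraction_per_batch: list[float] = field(default_factory=_default_case_fractions)
    n_probes: int = 5000
    n_signal_probes: int = 100
    effect_size_m: float = 0.5
    batch_mean_shift_sd: float = 1.0
    batch_var_scale_range: tuple[float, float] = (0.5, 2.0)
    n_celltypes: int = 6
    dirichlet_alpha_case: np.ndarray | None = None
    dirichlet_alpha_control: np.ndarray | None = None
    age_range: tuple[float, float] = (18.0, 65.0)
    sex_ratio: float = 0.65  # fraction female; females ~2x males pooled
    noise_sd: float = 0.5
    seed: int = 0
    confound_cells_with_status: bool = False
    confound_batch_with_status: bool = False
    missing_rate: float = 0.0  # optional MCAR mask

    def __post_init__(self) -> None:
        if self.n_batches <= 0 or self.n_probes <= 0 or self.n_celltypes <= 0:
            raise ValueError("counts must be positive")
        if self.n_signal_probes < 0 or self.n_signal_probes > self.n_probes:
            raise ValueError("n_signal_probes must be in [0, n_probes]")
        if len(self.samples_per_batch) != self.n_batches:
            raise ValueError("samples_per_batch must have length n_batches")
        if len(self.case_fraction_per_batch) != self.n_batches:
            raise ValueError("case_fraction_per_batch must have length n_batches")
        if any(n <= 0 for n in self.samples_per_batch):
            raise ValueError("samples_per_batch entries must be positive")
        if any(not 0 <= f <= 1 for f in self.case_fraction_per_batch):
            raise ValueError("case fractions must lie in [0, 1]")
        lo, hi = self.batch_var_scale_range
        if not 0 < lo <= hi:
            raise ValueError("batch_var_scale_range must satisfy 0 < low <= high")
        if self.dirichlet_alpha_control is None:
            base = np.array([_BLOOD_PROPORTIONS.get(ct, 1.0 / self.n_celltypes)
                             for ct in _celltype_names(self.n_celltypes)])
            self.dirichlet_alpha_control = 30.0 * base / base.sum()
        if self.dirichlet_alpha_case is None:
            alpha = np.asarray(self.dirichlet_alpha_control, dtype=float)
            if self.confound_cells_with_status:
                # shift mass toward the first cell type for cases
                tilt = np.ones(self.n_celltypes)
                tilt[0] = 2.0
                alpha = alpha * tilt
            self.dirichlet_alpha_case = alpha
        self.dirichlet_alpha_case = np.asarray(self.dirichlet_alpha_case, float)
        self.dirichlet_alpha_control = np.asarray(self.dirichlet_alpha_control, float)
        if (self.dirichlet_alpha_case.shape != (self.n_celltypes,)
                or self.dirichlet_alpha_control.shape != (self.n_celltypes,)):
            raise ValueError("Dirichlet alpha vectors must have length n_celltypes")


def _celltype_names(k: int) -> list[str]:
    if k <= len(DEFAULT_CELLTYPES):
        return list(DEFAULT_CELLTYPES[:k])
    return list(DEFAULT_CELLTYPES) + [f"CT{i}" for i in range(len(DEFAULT_CELLTYPES), k)]


@dataclass
class CellReferencePanel:
    """Reference beta profiles (celltype x probe) for deconvolution."""

    celltypes: list[str]
    reference_beta: pd.DataFrame  # rows = celltypes, columns = probe ids
    discriminating_probes: list[str]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.reference_beta.columns)


@dataclass
class GroundTruth:
    """Planted parameters of a simulated study: the acceptance oracle."""

    signal_probe_ids: set[str]
    per_probe_effect: dict[str, float]
    batch_shifts: dict[str, tuple[float, float]]  # batch -> (mean shift, var scale)
    cell_proportions: pd.DataFrame  # sample x celltype
    cell_reference: CellReferencePanel

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            signal_probe_ids=self.signal_probe_ids | other.signal_probe_ids,
            per_probe_effect={**self.per_probe_effect, **other.per_probe_effect},
            batch_shifts={**self.batch_shifts, **other.batch_shifts},
            cell_proportions=pd.concat([self.cell_proportions,
                                        other.cell_proportions]),
            cell_reference=self.cell_reference,
        )


def _probe_annotation(n_probes: int) -> pd.DataFrame:
    """Consecutive synthetic positions over the 22 autosomes."""
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    per_chrom = int(np.ceil(n_probes / len(AUTOSOMES)))
    chroms, pos = [], []
    for i in range(n_probes):
        chroms.append(AUTOSOMES[i // per_chrom])
        pos.append((i % per_chrom) * 100 + 1)  # 1-based
    return pd.DataFrame({"chrom": chroms, "pos": pos}, index=probe_ids)


def generate_reference_panel(n_probes: int, n_celltypes: int = 6,
                             seed: int = 0) -> CellReferencePanel:
    """Simulate a blood cell-type reference panel on the beta scale.

    The first min(200, n_probes//2) probes (at least 100 when n_probes
    allows) are built as discriminating probes: cell types are pushed to
    opposite beta extremes there so the between-celltype spread exceeds
    0.3, which is what makes constrained-projection deconvolution
    identifiable.
    """
    if n_probes <= 0 or n_celltypes < 2:
        raise ValueError("need n_probes > 0 and n_celltypes >= 2")
    rng = np.random.default_rng(seed)
    names = _celltype_names(n_celltypes)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    n_disc = min(max(100, n_probes // 10), n_probes // 2) if n_probes >= 4 else n_probes
    beta = rng.beta(0.5, 0.5, size=(n_celltypes, n_probes))
    # discriminating block: bimodal, each cell type assigned its own
    # high/low pattern so per-probe spread is large
    for j in range(n_disc):
        pattern = rng.integers(0, 2, size=n_celltypes)
        while pattern.min() == pattern.max():  # force both extremes present
            pattern = rng.integers(0, 2, size=n_celltypes)
        lows = rng.uniform(0.02, 0.15, size=n_celltypes)
        highs = rng.uniform(0.75, 0.98, size=n_celltypes)
        beta[:, j] = np.where(pattern == 1, highs, lows)
    ref = pd.DataFrame(beta, index=names, columns=probe_ids)
    return CellReferencePanel(celltypes=names, reference_beta=ref,
                              discriminating_probes=probe_ids[:n_disc])


def _simulate_samples(config: SimulationConfig, batch_name: str, n: int,
                      case_fraction: float, panel: CellReferencePanel,
                      shift: float, var_scale: float, signal_ids: list[str],
                      rng: np.random.Generator):
    """Build one batch worth of samples on the M scale."""
    n_cases = int(np.floor(case_fraction * n + 0.5))  # half-up rounding
    status = np.array(["case"] * n_cases + ["control"] * (n - n_cases))
    rng.shuffle(status)
    sample_ids = [f"{batch_name}_s{i:04d}" for i in range(n)]
    age = rng.uniform(*config.age_range, size=n).round(1)
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")

    # per-sample cell mixture -> mixed beta -> M baseline
    props = np.empty((n, config.n_celltypes))
    for i in range(n):
        alpha = (config.dirichlet_alpha_case if status[i] == "case"
                 else config.dirichlet_alpha_control)
        props[i] = rng.dirichlet(alpha)
    ref = panel.reference_beta.to_numpy()  # celltype x probe
    mixed_beta = props @ ref
    m = beta_to_m(mixed_beta)

    # planted case effect, batch location shift, batch-scaled noise
    probe_index = {p: j for j, p in enumerate(panel.probe_ids)}
    sig_cols = [probe_index[p] for p in signal_ids]
    is_case = status == "case"
    m[np.ix_(is_case, sig_cols)] += config.effect_size_m
    m += shift
    m += rng.normal(0.0, config.noise_sd * np.sqrt(var_scale), size=m.shape)
    if config.missing_rate > 0:
        mask = rng.random(m.shape) < config.missing_rate
        m[mask] = np.nan

    values = pd.DataFrame(m, index=sample_ids, columns=panel.probe_ids)
    samples = pd.DataFrame({"status": status, "age": age, "sex": sex,
                            "batch": batch_name}, index=sample_ids)
    prop_df = pd.DataFrame(props, index=sample_ids, columns=panel.celltypes)
    return values, samples, prop_df


def _batch_params(config: SimulationConfig, rng: np.random.Generator):
    """Draw (mean shift, variance scale) for every batch up front."""
    lo, hi = config.batch_var_scale_range
    shifts, scales = [], []
    for b in range(config.n_batches):
        if config.confound_batch_with_status:
            # location shift is a deterministic function of the batch's
            # case fraction: the ingredients of batch leakage
            shifts.append(4.0 * (config.case_fraction_per_batch[b] - 0.5)
                          * config.batch_mean_shift_sd)
        else:
            shifts.append(rng.normal(0.0, config.batch_mean_shift_sd)
                          if config.batch_mean_shift_sd > 0 else 0.0)
        scales.append(rng.uniform(lo, hi))
    return shifts, scales


def generate_batch(config: SimulationConfig, batch_index: int,
                   panel: CellReferencePanel | None = None,
                   seed: int | None = None):
    """Generate a single cohort batch and its ground truth.

    The M-value of sample i at probe j is built as
    ``logit2(w_i . R_j) + effect * case_i * 1[j is signal] + shift_b +
    noise`` with noise SD scaled by the batch variance factor.
    """
    if batch_index >= config.n_batches:
        raise ValueError("batch_index out of range")
    if panel is None:
        panel = generate_reference_panel(config.n_probes, config.n_celltypes,
                                         seed=config.seed)
    if len(panel.probe_ids) != config.n_probes:
        raise ValueError("panel probe count does not match config.n_probes")
    root = np.random.default_rng(config.seed if seed is None else seed)
    signal_ids = _signal_probe_ids(config, panel)
    shifts, scales = _batch_params(config, np.random.default_rng(root.integers(2**31)))
    batch_rngs = root.spawn(config.n_batches)
    name = f"batch{batch_index}"
    values, samples, props = _simulate_samples(
        config, name, config.samples_per_batch[batch_index],
        config.case_fraction_per_batch[batch_index], panel,
        shifts[batch_index], scales[batch_index], signal_ids,
        batch_rngs[batch_index])
    ds = MethylationDataset(values=values, scale="M", samples=samples,
                            probes=_probe_annotation(config.n_probes))
    truth = GroundTruth(
        signal_probe_ids=set(signal_ids),
        per_probe_effect={p: config.effect_size_m for p in signal_ids},
        batch_shifts={name: (shifts[batch_index], scales[batch_index])},
        cell_proportions=props,
        cell_reference=panel,
    )
    return ds, truth


def _signal_probe_ids(config: SimulationConfig,
                      panel: CellReferencePanel) -> list[str]:
    # signal probes avoid the discriminating block so deconvolution and
    # case effects stay orthogonal; chosen deterministically from the seed
    rng = np.random.default_rng(config.seed + 1_000_003)
    disc = set(panel.discriminating_probes)
    candidates = [p for p in panel.probe_ids if p not in disc]
    if len(candidates) < config.n_signal_probes:
        candidates = panel.probe_ids
    idx = rng.choice(len(candidates), size=config.n_signal_probes,
                     replace=False)
    return [candidates[i] for i in sorted(idx)]


def generate_study(config: SimulationConfig):
    """Generate all batches of a study sharing one probe universe.

    Returns (list of per-batch datasets, merged GroundTruth).
    """
    panel = generate_reference_panel(config.n_probes, config.n_celltypes,
                                     seed=config.seed)
    root = np.random.default_rng(config.seed)
    signal_ids = _signal_probe_ids(config, panel)
    shifts, scales = _batch_params(config, np.random.default_rng(root.integers(2**31)))
    batch_rngs = root.spawn(config.n_batches)
    datasets = []
    all_props = []
    for b in range(config.n_batches):
        name = f"batch{b}"
        values, samples, props = _simulate_samples(
            config, name, config.samples_per_batch[b],
            config.case_fraction_per_batch[b], panel, shifts[b], scales[b],
            signal_ids, batch_rngs[b])
        datasets.append(MethylationDataset(
            values=values, scale="M", samples=samples,
            probes=_probe_annotation(config.n_probes)))
        all_props.append(props)
    truth = GroundTruth(
        signal_probe_ids=set(signal_ids),
        per_probe_effect={p: config.effect_size_m for p in signal_ids},
        batch_shifts={f"batch{b}": (shifts[b], scales[b])
                      for b in range(config.n_batches)},
        cell_proportions=pd.concat(all_props),
        cell_reference=panel,
    )
    return datasets, truth
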