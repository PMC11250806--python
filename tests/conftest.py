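import numpy as np
import pandas as pd
import pytest

from methbench import MethylationDataset


def make_dataset(values, status=None, batch=None, scale="M", age=None,
                 sex=None, chrom=None):
    """Assemble a MethylationDataset from a raw matrix with defaults."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sids = [f"s{i:03d}" for i in range(n)]
    pids = [f"cg{i:05d}" for i in range(p)]
    rng = np.random.default_rng(12345)
    samples = pd.DataFrame({
        "status": status if status is not None else ["case", "control"] * (n // 2) + ["case"] * (n % 2),
        "age": age if age is not None else rng.uniform(20, 60, n).round(1),
        "sex": sex if sex is not None else list(rng.choice(["F", "M"], n)),
        "batch": batch if batch is not None else "batchA",
    }, index=sids)
    probes = pd.DataFrame({
        "chrom": chrom if chrom is not None else "chr1",
        "pos": np.arange(1, p + 1),
    }, index=pids)
    return MethylationDataset(values=pd.DataFrame(values, index=sids, columns=pids),
                              scale=scale, samples=samples, probes=probes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240715)


@pytest.fixture
def two_batch_null():
    """Two batches, 60 samples each, pure noise plus a location/scale shift."""
    r = np.random.default_rng(9)
    n, p = 60, 150
    Y = np.vstack([r.normal(0, 1, (n, p)), r.normal(1.0, np.sqrt(2.0), (n, p))])
    status = list(r.choice(["case", "control"], 2 * n))
    batch = ["A"] * n + ["B"] * n
    return make_dataset(Y, status=status, batch=batch)
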