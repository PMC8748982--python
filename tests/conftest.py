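import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gliatrap.containers import CountMatrix
from gliatrap.expression import compute_fpkm

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """A 6-gene, 2x3-sample matrix small enough to check by hand."""
    genes = [f"g{i}" for i in range(6)]
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(6, 6)),
        index=pd.Index(genes, name="gene_id"),
        columns=[f"WT_{i}" for i in range(3)] + [f"TG_{i}" for i in range(3)],
    )
    counts.iloc[5] = 0  # an all-zero gene
    lengths = pd.Series([1000, 2000, 500, 4000, 1500, 800], index=genes)
    samples = pd.DataFrame(
        {"genotype": ["WT"] * 3 + ["TG"] * 3, "region": "cortex", "stage": "late"},
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts=counts, lengths=lengths, samples=samples)


@pytest.fixture
def tiny_expr(tiny_counts):
    return compute_fpkm(tiny_counts)
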