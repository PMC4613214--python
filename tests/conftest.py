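import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from refstab import CqDataset, EfficiencyTable

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(gene_cq: dict, tissue: str = "leaf", conditions=None) -> CqDataset:
    """Build a single-tissue dataset from per-gene Cq lists.

    Each list position becomes its own biological sample; ``conditions``
    defaults to one condition per sample (c1, c2, ...).
    """
    n = len(next(iter(gene_cq.values())))
    if conditions is None:
        conditions = [f"c{i + 1}" for i in range(n)]
    rows = []
    for gene, values in gene_cq.items():
        assert len(values) == n
        for i, cq in enumerate(values):
            rows.append(
                {
                    "gene": gene,
                    "sample": f"s{i + 1}",
                    "tissue": tissue,
                    "condition": conditions[i],
                    "bio_rep": 1,
                    "cq": cq,
                }
            )
    return CqDataset(pd.DataFrame(rows))


def make_replicated_dataset(
    gene_cond_cq: dict, n_bio: int = 1, tissue: str = "leaf"
) -> CqDataset:
    """Dataset from per-gene, per-condition Cq values, replicated
    ``n_bio`` times (identical replicates)."""
    rows = []
    for gene, cond_map in gene_cond_cq.items():
        for cond, cq in cond_map.items():
            for b in range(1, n_bio + 1):
                rows.append(
                    {
                        "gene": gene,
                        "sample": f"{cond}:b{b}",
                        "tissue": tissue,
                        "condition": cond,
                        "bio_rep": b,
                        "cq": cq,
                    }
                )
    return CqDataset(pd.DataFrame(rows))


def random_dataset(rng, n_genes=4, n_samples=6, tissue="leaf") -> CqDataset:
    genes = [f"g{i}" for i in range(n_genes)]
    return make_dataset(
        {g: list(rng.uniform(20.0, 30.0, n_samples)) for g in genes}, tissue=tissue
    )


def uniform_eff(genes, value: float = 2.0) -> EfficiencyTable:
    return EfficiencyTable({g: value for g in genes})


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def tmp_path_shared(tmp_path_factory):
    """Session-scoped scratch dir, usable inside hypothesis-driven tests."""
    return tmp_path_factory.mktemp("shared")
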