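import numpy as np
import pandas as pd
import pytest

from sigmap import Compendium


def make_compendium(values, cell_types=None, datasets=None, species="human", scale="log2"):
    """Small Compendium from a 2D array; default one dataset, one type each."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = [f"g{i:03d}" for i in range(n_genes)]
    sample_ids = [f"s{j:02d}" for j in range(n_samples)]
    cell_types = cell_types or ["T"] * n_samples
    datasets = datasets or ["ds1"] * n_samples
    reps = {}
    ann = []
    for sid, ct, ds in zip(sample_ids, cell_types, datasets):
        reps[(ds, ct)] = reps.get((ds, ct), 0) + 1
        ann.append(
            {
                "sample_id": sid,
                "dataset_id": ds,
                "cell_type": ct,
                "species": species,
                "replicate_index": reps[(ds, ct)],
            }
        )
    return Compendium(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        samples=pd.DataFrame(ann).set_index("sample_id"),
        scale=scale,
    )


@pytest.fixture
def two_class_compendium():
    """6 genes x 6 samples, classes A/B (3 replicates each), exact values."""
    rng = np.random.default_rng(7)
    base = rng.normal(6, 1, (6, 1)) + rng.normal(0, 0.3, (6, 6))
    base[0, :3] += 2.0  # g000 up in A
    base[1, 3:] += 2.0  # g001 up in B
    return make_compendium(base, cell_types=["A"] * 3 + ["B"] * 3)


@pytest.fixture
def tiny_sim_config():
    from sigmap import SimulationConfig

    return SimulationConfig(
        n_genes=300, marker_count=15, cell_types=("cDC", "pDC", "Mono"), seed=5
    )
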