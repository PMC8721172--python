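import numpy as np
import pandas as pd
import pytest

import oodosage as oo


@pytest.fixture(scope="session")
def small_annotation() -> pd.DataFrame:
    return oo.make_annotation(n_autosomal=100, n_x=20, n_y=10, n_par=4,
                              n_spikes=92, seed=1)


@pytest.fixture(scope="session")
def samples() -> pd.DataFrame:
    return oo.make_samples(n_replicates=3)


@pytest.fixture(scope="session")
def small_truth(small_annotation) -> oo.TruthTable:
    return oo.simulate_truth(small_annotation, seed=2)


@pytest.fixture(scope="session")
def small_counts(small_truth, samples):
    counts, factors = oo.simulate_counts(small_truth, samples, seed=3)
    return counts, factors


def genotype_log_matrix(rng, n_genes, means_by_genotype, sdlog=0.2,
                        n_reps=3):
    """Log2 expression matrix with per-genotype true means (helper)."""
    cols, data = [], []
    for g, mu in means_by_genotype.items():
        for r in range(1, n_reps + 1):
            cols.append(f"{g}{r}")
            data.append(np.log2(mu) + rng.normal(0, sdlog, size=n_genes))
    idx = [f"g{i:05d}" for i in range(n_genes)]
    return pd.DataFrame(np.array(data).T, index=idx, columns=cols)
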