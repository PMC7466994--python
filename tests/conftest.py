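import numpy as np
import pandas as pd
import pytest

from poolgp import (
    generate_panel,
    impute_missing,
    kinship,
    simulate_frequencies,
    simulate_phenotypes,
)
from poolgp.dataio import AlleleFrequencyMatrix


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(60, seed=11)


@pytest.fixture(scope="session")
def small_freqs(small_panel):
    """60 populations x 300 markers with moderate IBD structure."""
    return simulate_frequencies(
        small_panel, n_scaffolds=30, markers_per_scaffold=10, seed=12
    )


@pytest.fixture(scope="session")
def small_imputed(small_freqs):
    return impute_missing(small_freqs)


@pytest.fixture(scope="session")
def small_G(small_imputed):
    return kinship(small_imputed)


@pytest.fixture(scope="session")
def small_trait(small_freqs):
    """Oligogenic high-heritability trait plus its ground truth."""
    records, truth = simulate_phenotypes(
        small_freqs, n_qtl=8, h2_pop=0.9, n_envs=2, n_blocks=3, gxe_share=0.2, seed=13
    )
    return records, truth


def toy_matrix(values, pop_ids=None, marker_ids=None, scaffolds=None, positions=None):
    """Hand-build a small AlleleFrequencyMatrix for exact-arithmetic tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    pop_ids = pop_ids or [f"p{i}" for i in range(n)]
    marker_ids = marker_ids or [f"m{j}" for j in range(p)]
    marker_map = pd.DataFrame(
        {
            "scaffold": scaffolds or ["s1"] * p,
            "pos_bp": positions or list(range(1, p + 1)),
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    return AlleleFrequencyMatrix(pop_ids, marker_ids, values, marker_map)
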