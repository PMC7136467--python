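import numpy as np
import pandas as pd
import pytest

from pigpopgen.genotype_io import (MARKER_COLUMNS, SAMPLE_COLUMNS,
                                   GenotypeDataset)


def make_dataset(calls, positions=None, chroms=None, populations=None,
                 alleles=("A", "G")):
    """Build a GenotypeDataset from a calls matrix with minimal metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    if positions is None:
        positions = (np.arange(L) + 1) * 100_000
    if chroms is None:
        chroms = np.ones(L, dtype=int)
    markers = pd.DataFrame(
        {"id": [f"snp{j + 1}" for j in range(L)], "chrom": chroms,
         "pos_bp": positions, "a1": alleles[0], "a2": alleles[1]},
        columns=MARKER_COLUMNS)
    if populations is None:
        populations = ["POP1"] * n
    samples = pd.DataFrame(
        {"sample_id": [f"ind{i + 1}" for i in range(n)],
         "population": populations, "sex": [0] * n},
        columns=SAMPLE_COLUMNS)
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


@pytest.fixture
def two_pop_dataset():
    """Small two-population Balding-Nichols panel with known truth."""
    from pigpopgen.synthetic_data import SimConfig, simulate_panel
    cfg = SimConfig(n_pops=2, drift=(0.3, 0.3), n_per_pop=(12, 12),
                    n_snps=1200, seed=42)
    ds, panel, truth = simulate_panel(cfg)
    return ds, panel, truth
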