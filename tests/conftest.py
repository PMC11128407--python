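import numpy as np
import pandas as pd
import pytest

from ldbayes import (GenotypeMatrix, PhenotypeTable, cluster_ld_blocks,
                     simulate_magic_genotypes)


def make_genotypes(calls, chrom=None, pos=None):
    """GenotypeMatrix from a plain call array with auto ids."""
    calls = np.asarray(calls, dtype=np.int8)
    n, p = calls.shape
    return GenotypeMatrix(
        [f"l{i}" for i in range(n)],
        np.array([f"s{j}" for j in range(p)], dtype=object),
        np.array(chrom if chrom is not None else ["1"] * p, dtype=object),
        np.arange(p) if pos is None else np.asarray(pos),
        calls)


def make_pheno(lines, values, env=1, trait="t"):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    rows = []
    for j in range(values.shape[1]):
        for i, line in enumerate(lines):
            if np.isnan(values[i, j]):
                continue  # unbalanced data: the record is simply absent
            rows.append((line, j + 1, trait, values[i, j]))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["line", "env", "trait", "value"]))


@pytest.fixture(scope="session")
def small_panel():
    """Small synthetic RIL panel with LD blocks, shared across tests."""
    g = simulate_magic_genotypes(n_lines=120, n_chrom=3, snps_per_chrom=60,
                                 seed=7)
    blocks = cluster_ld_blocks(g)
    return g, blocks
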