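import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from divgwas.genotypes import GenotypeData
from divgwas.pedigree import Pedigree
from divgwas.simdata import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Two-line selection run at desk scale, shared across tests."""
    cfg = SimConfig(
        n_generations=2, n_sires_per_line=6, n_dams_per_line=15, progeny_per_dam=4,
        n_snps=400, n_chromosomes=4, chrom_length_bp=40_000_000,
        qtl_spec=[("1", 5_000_000, 0.08, 0.10, 0.9)], seed=11,
    )
    return simulate(cfg)


@pytest.fixture
def trio_pedigree():
    return Pedigree.from_records(
        [("s", None, None), ("d", None, None), ("o1", "s", "d"), ("o2", "s", "d")]
    )


def make_genotypes(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    k = dosages.shape[1]
    smap = pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(k)],
        "chrom": chrom if chrom is not None else ["1"] * k,
        "pos_bp": pos if pos is not None else list(range(1000, 1000 + 1000 * k, 1000)),
    })
    ids = [f"a{i + 1}" for i in range(dosages.shape[0])]
    return GenotypeData(dosages, smap, ids)


@pytest.fixture
def toy_genotypes():
    rng = np.random.default_rng(5)
    return make_genotypes(rng.integers(0, 3, size=(20, 12)))
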