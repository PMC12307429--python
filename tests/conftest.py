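"""Shared fixtures: small synthetic panels and toy matrix builders."""

import numpy as np
import pandas as pd
import pytest

from germcore import genotype_matrix as gm
from germcore import synthetic_data as sd


def make_matrix(dosages, sample_ids=None, is_snp=True) -> gm.GenotypeMatrix:
    """Toy GenotypeMatrix from a plain dosage array (may contain -1)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    flags = [is_snp] * L if isinstance(is_snp, bool) else list(is_snp)
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, L + 1) * 10,
            "ref": ["A" if f else "AT" for f in flags],
            "alt": "G",
            "is_snp": flags,
            "n_alleles": 2,
        },
        index=pd.Index([f"l{j}" for j in range(L)], name="locus_id"),
    )
    return gm.GenotypeMatrix(sample_ids, loci, dosages)


@pytest.fixture(scope="session")
def small_config() -> sd.PopulationConfig:
    return sd.PopulationConfig(
        n_accessions=30, n_snps=400, n_indels=40, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config) -> gm.GenotypeMatrix:
    return sd.simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_filtered(small_panel) -> gm.GenotypeMatrix:
    filtered, _ = gm.site_filter(small_panel)
    return filtered


@pytest.fixture(scope="session")
def default_population():
    """One full-scale default panel shared by structure-level tests."""
    cfg = sd.PopulationConfig(seed=2)
    panel = sd.simulate_panel(cfg)
    filtered, _ = gm.site_filter(panel)
    return cfg, filtered
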