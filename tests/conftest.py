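import numpy as np
import pandas as pd
import pytest

from regulome_qtl.experiments import default_study_config
from regulome_qtl.simulate import simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Moderate default-design study shared by read-only tests."""
    cfg = default_study_config(seed=42, n_snps=200, n_cpgs=200, n_probes=100)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_annotations():
    """Tiny SNP/CpG annotation pair on two chromosomes for pair tests."""
    g = np.random.default_rng(7)
    snps = pd.DataFrame({
        "chrom": ["1"] * 6 + ["2"] * 4,
        "pos": g.integers(1, 1_000_000, 10),
    }, index=[f"snp{i}" for i in range(10)])
    cpgs = pd.DataFrame({
        "chrom": ["1"] * 5 + ["2"] * 5,
        "pos": g.integers(1, 1_000_000, 10),
    }, index=[f"cg{i}" for i in range(10)])
    return snps, cpgs
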