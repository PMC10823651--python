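import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrtri.summary import AssociationTable

settings.register_profile(
    "mrtri", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("mrtri")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_table(betas, ses, eafs=None, alleles=None, n=10_000, ids=None,
               trait="trait", sample="s"):
    """Helper to build small AssociationTables in tests."""
    k = len(betas)
    if eafs is None:
        eafs = [0.3] * k
    if alleles is None:
        alleles = [("A", "G")] * k
    if ids is None:
        ids = [f"rs{i}" for i in range(k)]
    df = pd.DataFrame({
        "variant_id": ids,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": eafs, "beta": betas, "se": ses, "n": n,
    })
    return AssociationTable(df, trait=trait, sample=sample)


@pytest.fixture
def table_factory():
    return make_table
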