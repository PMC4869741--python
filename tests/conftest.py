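import numpy as np
import pandas as pd
import pytest

from causalome.containers import GenotypeMatrix
from causalome.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact cohort with strong planted effects, reused read-only."""
    cfg = SimulationConfig(
        n_samples=2000,
        n_snps=40,
        n_ld_blocks=20,
        n_metabolites=8,
        dag_edge_prob=0.2,
        n_direct_parents=2,
        direct_effect_range=(0.2, 0.4),
        visit_sizes=(2000, 1200, 600),
        seed=7,
    )
    return cfg, simulate_study(cfg)


def make_genotypes(dosage_columns: dict, sample_prefix: str = "S") -> GenotypeMatrix:
    """GenotypeMatrix from raw dosage vectors keyed by variant id."""
    dosages = pd.DataFrame(dosage_columns, dtype=float)
    dosages.index = pd.Index(
        [f"{sample_prefix}{i}" for i in range(len(dosages))], name="sample_id"
    )
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, dosages.shape[1] + 1),
            "ref": "A",
            "alt": "G",
        },
        index=dosages.columns.rename("variant_id"),
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)
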