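import numpy as np
import pandas as pd
import pytest

from methnet import CohortConfig, generate_cohort

EQUAL_30 = {p: 30 for p in ("normal", "I", "II", "III", "IV")}


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with every planted feature, shared across tests."""
    cfg = CohortConfig(
        n_probes=150,
        n_genes=80,
        n_tfs=12,
        samples_per_phenotype=EQUAL_30,
        n_planted_pairs=15,
        n_regulated_targets=24,
        tfs_per_target=2,
        n_flipped_promoters_per_stage=6,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def toy_probes():
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(6)],
            "chrom": ["chr1", "chr1", "chr2", "chrX", "chrY", "chr3"],
            "position": [100, 5000, 200, 300, 400, 999],
            "masked": [False, True, True, False, False, False],
            "sex_chrom": [False, False, False, True, True, False],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
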