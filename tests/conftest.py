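import numpy as np
import pandas as pd
import pytest

from longgxe.regions import GenotypeMatrix
from longgxe.simulate import (
    RegionSpec,
    SimulationConfig,
    hrs_ea_like,
    simulate_cohort,
    simulate_genotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort():
    """400 subjects, 20 variants, moderate LD, no genetic effects."""
    cfg = hrs_ea_like(
        n_subjects=400, region=RegionSpec(p=20, rho=0.5), seed=11
    )
    gen = np.random.default_rng(cfg.seed)
    gm = simulate_genotypes(cfg.n_subjects, cfg.region, gen)
    table = simulate_cohort(cfg, gm, gen)
    return cfg, gm, table


@pytest.fixture
def toy_genotypes():
    """5 subjects x 4 variants with hand-set dosages and metadata."""
    meta = pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3", "v4"],
            "chrom": "1",
            "pos": [100, 200, 300, 400],
            "ref": ["A", "A", "A", "A"],
            "alt": ["C", "G", "T", "C"],
            "info": [0.9, 0.9, 0.4, 0.95],
        }
    )
    dosages = np.array(
        [
            [0.0, 1.0, 2.0, 0.0],
            [1.0, 1.0, 1.0, 0.0],
            [2.0, 0.0, 0.0, 0.1],
            [1.0, 2.0, 1.0, 0.0],
            [0.0, 1.0, 2.0, 0.0],
        ]
    )
    return GenotypeMatrix(["s1", "s2", "s3", "s4", "s5"], meta, dosages)
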