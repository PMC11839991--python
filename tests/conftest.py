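import numpy as np
import pytest

from rvcollapse.simulate import (
    CohortSpec,
    GeneEffectSpec,
    SimulationConfig,
    SomaticGeneSpec,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_config():
    """A two-cohort study with one risk gene, one null gene and a planted
    somatic-contamination gene, small enough to run the full VCF pipeline."""
    return SimulationConfig(
        seed=20260924,
        cohorts=(
            CohortSpec("COHA", n_cases=250, n_controls=500, aggressive_fraction=0.3),
            CohortSpec("COHB", n_cases=150, n_controls=300, aggressive_fraction=0.3),
        ),
        genes=(
            GeneEffectSpec("RISKG", control_carrier_freq=0.01, odds_ratio_risk=5.0),
            GeneEffectSpec("NULLG", control_carrier_freq=0.01, odds_ratio_risk=1.0),
        ),
        qc_fail_fraction=0.2,
        somatic_gene=SomaticGeneSpec(
            "SOMG", age_slope_per_year=0.15, mean_alt_fraction=0.3, base_carrier_freq=0.02
        ),
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    return simulate_study(small_config, tmp_path_factory.mktemp("study"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
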