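import numpy as np
import pandas as pd
import pytest

from gxegrowth import EnvironmentSpec, GenotypeMatrix, relationship_matrix, simulate_study
from gxegrowth.simulate import FieldSite, SimScenario, TempModel, simulate_genotypes


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    """Desk-scale trial: 24 cultivars, 60 loci, 4 training environments."""
    mf = FieldSite("MF", 31.8, {2019: (160, 200)})
    tf = FieldSite("TF", 38.5, {2019: (155, 195)})
    kf = FieldSite("KF", 35.3, {2020: (165, 205)})
    return SimScenario(
        n_cultivars=24,
        n_loci=60,
        n_chromosomes=4,
        chrom_length_bp=5_000_000,
        fields=(mf, tf),
        test_fields=(kf,),
        n_test_cultivars=12,
        obs_weeks=10,
        n_replicates=2,
    )


@pytest.fixture(scope="session")
def small_study(small_scenario):
    return simulate_study(small_scenario, seed=42)


@pytest.fixture(scope="session")
def small_geno(small_study) -> GenotypeMatrix:
    return small_study.genotypes


def constant_temp_env(name: str, temp: float, latitude: float = 35.0,
                      sowing_doy: int = 160, year: int = 2019, n_days: int = 150) -> EnvironmentSpec:
    """An environment with a flat daily temperature series (exact T windows)."""
    return EnvironmentSpec(
        name=name,
        field=name.split("-")[0],
        latitude=latitude,
        year=year,
        sowing_doy=sowing_doy,
        temperatures=np.full(n_days, float(temp)),
    )
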