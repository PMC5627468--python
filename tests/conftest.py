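import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from epiqus import (
    CovariateTable,
    GenotypeMatrix,
    SimulationConfig,
    SnpMarker,
    load_reference_panel,
)


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture
def two_markers():
    return [
        SnpMarker("rsA", "1", "GENEA", "G", "A", 0.3),
        SnpMarker("rsB", "2", "GENEB", "C", "T", 0.2),
    ]


def make_matrix(dosages, markers=None, sample_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if markers is None:
        markers = [
            SnpMarker(f"rs{j}", "1", f"G{j}", "A", "C", 0.3) for j in range(m)
        ]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, markers=markers, dosages=dosages)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort with planted main and interaction effects."""
    from epiqus import InteractionEffect, MainEffect, generate_cohort

    cfg = SimulationConfig(
        n_samples=800,
        seed=11,
        missing_rate=0.0,
        snp_effects=[MainEffect("rs9340799", 3.0), MainEffect("rs3736228", -2.0)],
        interaction_effects=[InteractionEffect("rs9340799", "rs3736228", 8.0)],
    )
    return cfg, generate_cohort(cfg)
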