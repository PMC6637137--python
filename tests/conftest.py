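import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import exonsi

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params() -> exonsi.SimulationParams:
    """A small but structurally complete simulation configuration."""
    return exonsi.SimulationParams(
        n_genes=40,
        exons_per_gene=(4, 6),
        transcripts_per_gene=(2, 3),
        n_subjects=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """Design, cohort and simulated intensities shared across read-only tests."""
    design = exonsi.make_design(small_params)
    cohort = exonsi.simulate_cohort(small_params)
    expr = exonsi.simulate_intensities(design, cohort, small_params)
    return design, cohort, expr


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def probe_matrix_from(values: np.ndarray, probes, samples) -> exonsi.IntensityMatrix:
    return exonsi.IntensityMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples), level="probe"
    )
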