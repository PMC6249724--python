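import numpy as np
import pandas as pd
import pytest

from physiodys import default_config, generate_cohort, make_fixtures
from physiodys.pipeline import PANEL_VARIABLES, RunConfig, run_pipeline
from physiodys.preprocess import (DEFAULT_TRANSFORM_MAP, immune_composite,
                                  normalize_variables, oxidative_composite,
                                  standardize_by_cell)


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=11)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(default_config(), seed=42)


@pytest.fixture(scope="session")
def standardized_panel(cohort):
    """Transformed, composite-augmented, cell-standardized panel."""
    data, _ = normalize_variables(cohort, DEFAULT_TRANSFORM_MAP)
    nab = immune_composite(data["agglutination"], data["lysis"])
    ox = oxidative_composite(data["oxy"], data["droms"])
    data = pd.concat([data, nab.scores, ox.scores], axis=1)
    return standardize_by_cell(data, PANEL_VARIABLES)


@pytest.fixture(scope="session")
def pipeline_report():
    """Full end-to-end run on one seed, shared by structure checks."""
    return run_pipeline(RunConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
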