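import numpy as np
import pandas as pd
import pytest

from artgrowth import GeneratorConfig, analysis_frame, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort draw under the default study conditions."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def frame72(default_cohort):
    """Subject table with the 72-month outcome merged in."""
    return analysis_frame(default_cohort, month=72)


@pytest.fixture(scope="session")
def large_single_visit_cohort():
    """A larger cohort observed at a single visit (full effect multiplier),
    used by parameter-recovery checks."""
    cfg = GeneratorConfig(seed=3, n_treated=200, n_untreated=1800,
                          visit_schedule=(72,))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def frame_large(large_single_visit_cohort):
    return analysis_frame(large_single_visit_cohort, month=72)
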