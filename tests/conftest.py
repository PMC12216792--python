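import numpy as np
import pytest

from boldmaze.pipeline import RunConfig, build_cohort_table, run_pipeline
from boldmaze.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 46-fish synthetic cohort (seed 7), shared across tests."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """A complete pipeline run on the default synthetic cohort."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(out_dir=str(out), seed=7, generator=GeneratorConfig())
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_tables(default_cohort):
    """(cohort_table, binned) computed from the shared cohort."""
    cfg = RunConfig(out_dir="unused", seed=7, generator=GeneratorConfig())
    return build_cohort_table(default_cohort, cfg)


def brute_force_tetragrams(tokens):
    """Independent oracle: enumerate every length-4 window explicitly."""
    counts = {}
    for i in range(len(tokens)):
        window = "".join(tokens[i:i + 4])
        if len(window) == 4:
            counts[window] = counts.get(window, 0) + 1
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
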