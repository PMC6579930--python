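"""Shared fixtures: a DC-enriched synthetic cohort at unit-test scale.

Unit tests use a config with boosted DC frequencies so that every subset
carries enough events for tight statistical checks at small sample sizes;
cohort-level recovery of the reported (rare) frequencies is exercised in
the acceptance tests at full scale.
"""

import numpy as np
import pytest

from dcflow import (SpilloverMatrix, build_default_healthy_config,
                    simulate_sample, with_population_frequencies)
from dcflow.pipeline import ProcessedSample, process_sample

SEED = 11


@pytest.fixture(scope="session")
def boosted_config():
    cfg = build_default_healthy_config(seed=SEED, n_events=20_000)
    return with_population_frequencies(
        cfg, {"pDC": 0.05, "cDC1": 0.03, "cDC2": 0.12, "cDC_other": 0.02,
              "slanDC": 0.05, "moDC": 0.01})


@pytest.fixture(scope="session")
def true_spill(boosted_config):
    return SpilloverMatrix(boosted_config.spillover,
                           list(boosted_config.panel.detectors))


@pytest.fixture(scope="session")
def boosted_sample(boosted_config):
    return simulate_sample(boosted_config, 0, "basal", seed=SEED)


@pytest.fixture(scope="session")
def processed(boosted_config, boosted_sample, true_spill) -> ProcessedSample:
    return process_sample(boosted_sample, true_spill)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
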