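"""Shared fixtures: the default synthetic benchmark and reduced configs.

The default benchmark (seed 1, 40 participants, 178 sessions) is expensive
to build, so it is generated once per session and shared by the
acceptance-level tests. Unit tests use small bespoke configs instead.
"""

import numpy as np
import pytest
from hypothesis import settings

from accelval import experiments as ex
from accelval import features as ft
from accelval import labels as lb
from accelval import synthetic as syn
from accelval.labels import ActivityMeta

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_config():
    return ex.ExperimentConfig(benchmark=syn.SyntheticConfig(seed=1), seed=1)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    return syn.generate_benchmark(default_config.benchmark)


@pytest.fixture(scope="session")
def features16_smartwatch(default_bundle):
    return ex.benchmark_features(default_bundle, "smartwatch", 16.0)


@pytest.fixture(scope="session")
def features16_actigraph(default_bundle):
    return ex.benchmark_features(default_bundle, "actigraph", 16.0)


@pytest.fixture(scope="session")
def rf_results_smartwatch(default_bundle, features16_smartwatch):
    """Headline random-forest results for all five tasks, one device."""
    taxonomy = default_bundle.config.taxonomy
    return {
        task: ex.evaluate_task(
            features16_smartwatch, taxonomy, task, "random_forest", seed=1
        )
        for task in lb.TASKS
    }


def small_taxonomy() -> dict[str, ActivityMeta]:
    """Five-activity subset with short sessions, for fast pipeline tests."""
    full = lb.load_taxonomy()
    names = ["Computer work", "Ironing", "Mopping", "Leisure walk", "Heavy lifting"]
    return {
        n: ActivityMeta(
            name=n,
            body_location=full[n].body_location,
            intensity=full[n].intensity,
            locomotion=full[n].locomotion,
            duration=2.0,
            n_participants=full[n].n_participants,
        )
        for n in names
    }


@pytest.fixture()
def small_config():
    tax = small_taxonomy()
    return syn.SyntheticConfig(
        seed=7,
        n_participants=20,
        taxonomy=tax,
        models={n: syn.DEFAULT_ACTIVITY_MODELS[n] for n in tax},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
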