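import pytest

from mtqsar import CPIModel, SuiteConfig, generate_benchmark


def fast_suite_config(**extra) -> SuiteConfig:
    """Cheap hyperparameters for structural unit tests.

    Suite shape, vote plumbing and determinism do not depend on model
    strength, so unit tests shrink the forests and NN budget; the
    acceptance tests run the real defaults.
    """
    hp = {
        "RF": {"n_estimators": 40},
        "NN": {"max_iter": 200},
    }
    return SuiteConfig(hyperparameters=hp, **extra)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Two synthetic targets, 60 compounds each."""
    return generate_benchmark(n_targets=2, n_compounds_per_target=60, seed=11)


@pytest.fixture(scope="session")
def tiny_results(tiny_benchmark):
    """A fitted two-target suite shared across structural tests."""
    model = CPIModel(tiny_benchmark.datasets, tiny_benchmark.sequences,
                     fast_suite_config())
    return model.fit(seed=5)
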