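import numpy as np
import pytest

from dermstack import synthdata as sd


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small uniform-mix synthetic cohort shared across tests."""
    cfg = sd.SynthConfig(n_samples=36, class_mix=(1 / 6,) * 6, seed=7)
    return sd.generate_dataset(cfg)


@pytest.fixture(scope="session")
def strong_e2e():
    """The full stacked protocol on the strong-signal cohort (n=600).

    Session-scoped: the end-to-end run is shared by every test that asserts
    on held-out accuracies so the expensive feature extraction happens once.
    """
    from dermstack import pipeline as pl

    cfg = sd.SynthConfig.strong_signal(n_samples=600, seed=11)
    ds = sd.generate_dataset(cfg)
    results = pl.run_protocol(ds.images, ds.metadata, pl.PipelineConfig(seed=11))
    results["dataset"] = ds
    return results
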