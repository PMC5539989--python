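import warnings

import pytest

import varcallkit as vk


@pytest.fixture(scope="session")
def small_sim():
    """A compact, well-separated synthetic dataset with ground truth."""
    config = vk.GeneratorConfig(n_variants=20, n_labeled=6, seed=11)
    dataset, truth, labels = vk.generate(config)
    return config, dataset, truth, labels


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A converged fit of the small dataset (short chains are enough here)."""
    _, dataset, truth, labels = small_sim
    spec = vk.ModelSpec(chains=2, iterations=1200, burn_in=600, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", vk.model.ConvergenceWarning)
        fit = vk.fit(dataset, labels, spec)
    return fit


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study design (60 variants, 4 batches)."""
    dataset, truth, labels = vk.generate(vk.GeneratorConfig())
    return dataset, truth, labels
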