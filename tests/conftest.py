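import numpy as np
import pytest

from dcmerf import (ERFModel, InversionSettings, NetworkSpec, ParameterSet,
                    build_parameter_priors, subnetwork)


@pytest.fixture(scope="session")
def full_net():
    return NetworkSpec()


@pytest.fixture(scope="session")
def single_source_net(full_net):
    """One-source network: fast enough for inversion-level unit tests."""
    return subnetwork(full_net, ["lA1"])


@pytest.fixture(scope="session")
def single_source_model(single_source_net):
    return ERFModel(single_source_net)


@pytest.fixture(scope="session")
def single_source_prior(single_source_net):
    return build_parameter_priors(single_source_net,
                                  free_classes=("intrinsic_gaba", "input"))


@pytest.fixture(scope="session")
def recovered_posterior(single_source_model, single_source_prior):
    """One cached low-noise inversion shared by several tests."""
    from dcmerf import invert

    prior = single_source_prior
    model = single_source_model
    rng = np.random.default_rng(42)
    theta_true = rng.uniform(-1, 1, prior.p) * prior.sd()
    clean = model.simulate_dataset(ParameterSet(prior.names, theta_true))
    noise = 0.03 * np.abs(clean.erf).max()
    data = clean.with_erf(clean.erf + rng.normal(0, noise, clean.erf.shape),
                          conditioned=False)
    post = invert(data, model, prior, InversionSettings())
    return {"theta_true": theta_true, "data": data, "posterior": post,
            "clean": clean}
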