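"""Shared fixtures: the default synthetic experiment, built once per session.

All fixtures follow the pipeline's seed-derivation scheme with global seed
0, so tests exercise exactly the configuration the command-line pipeline
runs by default.
"""

import numpy as np
import pytest

from snnmanifold import (ArchitectureSpec, NeuronConfig, SyntheticTaskConfig,
                         TrainingConfig, build_network, make_static_task,
                         train)
from snnmanifold.encoding import poisson_encode_batch
from snnmanifold.reporting import derive_seed

GLOBAL_SEED = 0
T_STEPS = 10


@pytest.fixture(scope="session")
def default_dataset():
    return make_static_task(
        SyntheticTaskConfig(seed=derive_seed(GLOBAL_SEED, "synth")))


@pytest.fixture(scope="session")
def small_mlp_spec():
    return ArchitectureSpec(kind="mlp", input_shape=144, hidden_sizes=(32,),
                            n_classes=4)


@pytest.fixture(scope="session")
def default_neuron():
    return NeuronConfig(tau_m=2.0, v_th=1.0)


@pytest.fixture(scope="session")
def encoded_splits(default_dataset):
    ds = default_dataset
    xtr = poisson_encode_batch(ds.train_x.reshape(len(ds.train_y), -1),
                               T_STEPS, derive_seed(GLOBAL_SEED, "encode_train"))
    xte = poisson_encode_batch(ds.test_x.reshape(len(ds.test_y), -1),
                               T_STEPS, derive_seed(GLOBAL_SEED, "encode_test"))
    return xtr, xte


@pytest.fixture(scope="session")
def trained_mlp(default_dataset, small_mlp_spec, default_neuron,
                encoded_splits):
    """The reference trained model of the default experiment."""
    xtr, _ = encoded_splits
    net = build_network(small_mlp_spec, default_neuron,
                        seed=derive_seed(GLOBAL_SEED, "build"))
    history = train(net, xtr, default_dataset.train_y,
                    TrainingConfig(T=T_STEPS, epochs=15, batch_size=32,
                                   seed=derive_seed(GLOBAL_SEED, "train")))
    return net, history
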