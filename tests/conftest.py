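"""Shared fixtures.

Heavy scaled-down experiments (stairs learning comparison, maze novelty
run) are session-scoped so the acceptance tests can share one run.
"""

import numpy as np
import pytest

from spikevar.core_dynamics import DualNetwork, NeuronParams
from spikevar.experiments import TrainingProtocol, stairs_source, train
from spikevar.inference_eval import estimate_log_likelihood
from spikevar.learning_rules import LearnerConfig
from spikevar.synthetic_data import StairsConfig, stairs_raster


@pytest.fixture
def params():
    return NeuronParams()


@pytest.fixture
def enumerable_net():
    """2 visible / 2 hidden network with random weights, small enough to
    enumerate every hidden raster over a few bins."""
    return DualNetwork.random_init(2, 2, weight_sd=0.3, seed=11)


@pytest.fixture
def enumerable_clamp():
    rng = np.random.default_rng(5)
    return (rng.random((2, 4)) < 0.4).astype(np.uint8)


@pytest.fixture(scope="session")
def stairs_runs():
    """Scaled-down stairs learning comparison shared by the acceptance
    tests: 30 visible + 12 hidden neurons, 2000 batches of 200 ms.

    Returns final importance-sampling log-likelihoods (and divergence
    flags) for the visible-only model and the online, variance-reduced
    batch and naive batch hidden-neuron models, all trained on identical
    data streams from the same initial weights.
    """
    cfg_s = StairsConfig()
    eval_data = stairs_raster(cfg_s, 500, seed=999).spikes
    src = stairs_source(cfg_s, 200)

    out = {}
    for variant, n_hidden in (("fully_observed", 0), ("online", 12),
                              ("vr_batch", 12), ("naive_batch", 12)):
        net = DualNetwork.random_init(30, n_hidden, seed=20)
        cfg = LearnerConfig(mu_g=5e-5, mu_q=1e-7, variant=variant,
                            q_burn_in=50)
        protocol = TrainingProtocol(presentations_per_epoch=100, n_epochs=20,
                                    eval_every_epochs=10**9, seed=3)
        net, log = train(net, src, protocol, variant=variant, cfg=cfg)
        est = estimate_log_likelihood(net, eval_data, n_samples=100,
                                      sample_duration_bins=100, seed=77)
        out[variant] = {"loglik": est.log_likelihood,
                        "se": est.standard_error,
                        "diverged": log["diverged"],
                        "n_batches": len(log["batch_log"])}
    return out


@pytest.fixture(scope="session")
def maze_run():
    """Scaled-down maze novelty experiment shared by the acceptance tests:
    2x2 rooms, 8x8 views, 2 rooms replaced, online rule."""
    from spikevar.experiments import novelty_experiment
    from spikevar.synthetic_data import MazeConfig

    maze_cfg = MazeConfig(grid_shape=(2, 2), image_shape=(8, 8),
                          n_replaced_rooms=2)
    protocol = TrainingProtocol(presentations_per_epoch=50, n_epochs=100,
                                eval_every_epochs=10**9, seed=43)
    cfg = LearnerConfig(mu_g=5e-4, mu_q=1e-6, variant="online")
    return novelty_experiment(maze_cfg, n_hidden=10, protocol=protocol,
                              steps_per_batch=100, probe_every_epochs=50,
                              probe_steps=4000, final_probe_steps=20000,
                              cfg=cfg, seed=42)
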