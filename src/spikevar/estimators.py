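"""Scikit-learn-style estimators wrapping the spiking generative models.

Rasters are passed as arrays of shape ``(n_neurons, n_bins)`` or
``(n_batches, n_neurons, n_bins)``; a 2-D raster is split into batches of
``batch_bins`` columns.  Both estimators expose ``fit`` / ``score`` /
``sample`` and compose with sklearn model selection through
``get_params`` / ``set_params``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .core_dynamics import (DualNetwork, NeuronParams, SpikeRaster,
                            trace_from_raster)
from .experiments import TrainingProtocol, train
from .free_energy import complete_log_likelihood
from .inference_eval import (estimate_log_likelihood, infer_hidden,
                             sample_generative)

__all__ = ["FullyObservedSRM", "VariationalSpikingNetwork"]


def _as_batches(X, batch_bins: int) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 2:
        n_batches = X.shape[1] // batch_bins
        if n_batches < 1:
            raise ValueError("raster shorter than one batch")
        X = np.stack([X[:, k * batch_bins:(k + 1) * batch_bins]
                      for k in range(n_batches)])
    if X.ndim != 3:
        raise ValueError("X must be a 2-D raster or a 3-D stack of batches")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("raster entries must be 0 or 1")
    return X.astype(np.uint8)


class FullyObservedSRM(BaseEstimator):
    """Maximum-likelihood recurrent SRM network with no hidden neurons.

    Gradient ascent on the (convex) point-process log-likelihood of the
    observed raster.  ``score`` returns the mean log-likelihood per batch;
    ``sample`` draws spontaneous activity from the fitted network.
    """

    def __init__(self, learning_rate: float = 1e-4, n_epochs: int = 5,
                 batch_bins: int = 200, params: Optional[NeuronParams] = None,
                 random_state: Optional[int] = None):
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_bins = batch_bins
        self.params = params
        self.random_state = random_state

    def fit(self, X, y=None):
        from .learning_rules import LearnerConfig
        batches = _as_batches(X, self.batch_bins)
        n_neurons = batches.shape[1]
        p = self.params or NeuronParams()
        net = DualNetwork.random_init(n_neurons, 0, params=p,
                                      seed=self.random_state)
        rng_data = np.random.default_rng(self.random_state)

        def source(rng):
            return batches[int(rng_data.integers(len(batches)))]

        protocol = TrainingProtocol(
            batch_ms=self.batch_bins * p.dt,
            presentations_per_epoch=len(batches),
            n_epochs=self.n_epochs, eval_every_epochs=10**9,
            seed=self.random_state)
        cfg = LearnerConfig(mu_g=self.learning_rate, mu_q=self.learning_rate,
                            variant="fully_observed")
        train(net, source, protocol, variant="fully_observed", cfg=cfg)
        self.net_ = net
        self.w_ = net.w_g
        self.n_neurons_ = n_neurons
        return self

    def score(self, X, y=None) -> float:
        """Mean complete-data log-likelihood per batch (nats)."""
        batches = _as_batches(X, self.batch_bins)
        total = 0.0
        for b in batches:
            trace = trace_from_raster(self.net_, SpikeRaster(b, dt=self.net_.params.dt))
            total += complete_log_likelihood(trace, "G")
        return total / len(batches)

    def sample(self, n_bins: int, seed=None) -> SpikeRaster:
        return sample_generative(self.net_, n_bins, seed=seed).raster


class VariationalSpikingNetwork(BaseEstimator):
    """Recurrent spiking generative model with hidden neurons, fitted by
    stochastic variational free-energy descent.

    Parameters select the rule variant (``naive_batch``, ``vr_batch``,
    ``online`` or ``simplified``) and the learning rates of the generative
    and recognition synapse sets.  ``score`` returns the importance-
    sampling estimate of the visible log-likelihood; ``sample`` draws
    spontaneous activity; ``infer`` samples hidden explanations for given
    data from the recognition network.
    """

    def __init__(self, n_hidden: int = 10, variant: str = "vr_batch",
                 mu_g: float = 1e-5, mu_q: float = 1e-5,
                 tau_g: float = 10.0, tau_baseline: float = 100.0,
                 n_epochs: int = 1, batch_bins: int = 200,
                 eval_samples: int = 100, eval_bins: int = 100,
                 params: Optional[NeuronParams] = None,
                 random_state: Optional[int] = None):
        self.n_hidden = n_hidden
        self.variant = variant
        self.mu_g = mu_g
        self.mu_q = mu_q
        self.tau_g = tau_g
        self.tau_baseline = tau_baseline
        self.n_epochs = n_epochs
        self.batch_bins = batch_bins
        self.eval_samples = eval_samples
        self.eval_bins = eval_bins
        self.params = params
        self.random_state = random_state

    def _config(self):
        from .learning_rules import LearnerConfig
        return LearnerConfig(mu_g=self.mu_g, mu_q=self.mu_q, tau_g=self.tau_g,
                             tau_baseline=self.tau_baseline,
                             variant=self.variant)

    def fit(self, X, y=None):
        batches = _as_batches(X, self.batch_bins)
        n_visible = batches.shape[1]
        p = self.params or NeuronParams()
        net = DualNetwork.random_init(n_visible, self.n_hidden, params=p,
                                      seed=self.random_state)
        rng_data = np.random.default_rng(self.random_state)

        def source(rng):
            return batches[int(rng_data.integers(len(batches)))]

        protocol = TrainingProtocol(
            batch_ms=self.batch_bins * p.dt,
            presentations_per_epoch=len(batches),
            n_epochs=self.n_epochs, eval_every_epochs=10**9,
            seed=self.random_state)
        _, log = train(net, source, protocol, variant=self.variant,
                       cfg=self._config())
        self.net_ = net
        self.w_g_ = net.w_g
        self.w_q_ = net.w_q
        self.n_visible_ = n_visible
        self.train_log_ = log["batch_log"]
        return self

    def score(self, X, y=None) -> float:
        """Importance-sampling log-likelihood of the visible raster (nats)."""
        X = np.asarray(X)
        if X.ndim == 3:
            X = np.concatenate(list(X), axis=1)
        est = estimate_log_likelihood(self.net_, X, n_samples=self.eval_samples,
                                      sample_duration_bins=self.eval_bins,
                                      seed=self.random_state)
        return est.log_likelihood

    def sample(self, n_bins: int, seed=None) -> SpikeRaster:
        return sample_generative(self.net_, n_bins, seed=seed).raster

    def infer(self, X, seed=None) -> SpikeRaster:
        """Hidden raster sampled from the recognition network given data."""
        trace = infer_hidden(self.net_, np.asarray(X), seed=seed)
        return SpikeRaster(trace.raster.spikes[self.n_visible_:],
                           dt=self.net_.params.dt)
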