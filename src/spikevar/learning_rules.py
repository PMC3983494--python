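"""Synaptic plasticity rules minimizing the variational free energy.

Four variants are implemented on top of the same two-factor building block
(a postsynaptic spike-prediction-error factor times the presynaptic EPSP
trace):

- ``fully_observed``  — maximum-likelihood gradient ascent for a network
  with no hidden neurons (a convex problem);
- ``naive_batch``     — stochastic free-energy descent where the
  recognition-weight (Q) update is a score-function (REINFORCE) estimator
  modulated by the windowed free energy;
- ``vr_batch``        — the same with a moving-average baseline subtracted
  from the modulator, which leaves the expected update unchanged but
  reduces its variance from roughly quadratic to roughly linear growth in
  the network size;
- ``online``          — per-bin updates driven by low-pass-filtered Hebbian
  traces and the running novelty signal e_N(t) (a three-factor rule);
- ``simplified``      — a merged network where the recognition weights are
  tied to the generative weights and the objective keeps visible terms
  only.

Sign conventions perform descent on the free energy: generative weights
move up their likelihood gradient, recognition weights move opposite the
novelty-modulated Hebbian trace, so positive covariance between trace and
free energy depresses the synapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_dynamics import (DualNetwork, NetworkTrace, SimulationState,
                            SpikeRaster, firing_intensity)
from .free_energy import (FreeEnergyTracker, instantaneous_free_energy,
                          windowed_free_energy)

__all__ = [
    "LearnerConfig",
    "HebbianTraces",
    "post_factor",
    "fully_observed_gradient",
    "naive_batch_update",
    "variance_reduced_update",
    "online_step",
    "simplified_step",
    "run_online_batch",
    "variance_scaling_experiment",
]

VARIANTS = ("naive_batch", "vr_batch", "online", "simplified", "fully_observed")


@dataclass
class LearnerConfig:
    """Learning hyper-parameters.

    Defaults mirror the simulation conditions: learning rates 1e-5 for both
    synapse sets, 10 ms gradient/free-energy averaging time constant,
    100 ms baseline time constant, 200 ms batches.  ``baseline_decay`` sets
    the exponential moving average used as the batch baseline (0.1 gives an
    effective window of about ten batches).

    ``q_burn_in`` delays recognition-weight updates for the first few
    batches so the free-energy baseline settles before the score-function
    estimator starts drawing on it; while generative learning moves fast
    (scaled-up rates on short runs), the trailing baseline lags the
    steeply decreasing free energy and the error signal would otherwise be
    dominated by that trend.
    """

    mu_g: float = 1e-5
    mu_q: float = 1e-5
    tau_g: float = 10.0
    tau_baseline: float = 100.0
    variant: str = "vr_batch"
    batch_ms: float = 200.0
    baseline_decay: float = 0.1
    form: str = "continuous_limit"
    q_burn_in: int = 0

    def __post_init__(self) -> None:
        if self.mu_g <= 0 or self.mu_q <= 0:
            raise ValueError("learning rates must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0 < self.baseline_decay <= 1:
            raise ValueError("baseline_decay must be in (0, 1]")


@dataclass
class HebbianTraces:
    """Low-pass-filtered pre/post coincidence traces, one per synapse set."""

    h_g: np.ndarray
    h_q: np.ndarray
    tau_g: float = 10.0

    @classmethod
    def zeros(cls, net: DualNetwork, tau_g: float = 10.0) -> "HebbianTraces":
        n = net.n_neurons
        return cls(h_g=np.zeros((n, n)), h_q=np.zeros((n, n)), tau_g=tau_g)

    def copy(self) -> "HebbianTraces":
        return HebbianTraces(self.h_g.copy(), self.h_q.copy(), self.tau_g)


def post_factor(trace: NetworkTrace, which: str = "G",
                neuron: Optional[int] = None, t_bin: Optional[int] = None,
                form: str = "continuous_limit"):
    """Postsynaptic factor of the plasticity rule.

    For the exponential escape rate the log-derivative of the rate function
    is 1/delta_u, so the continuous-limit factor is
    ``(X - rho*dt) / delta_u`` — a spike-prediction error: positive right
    after a spike, slightly negative otherwise, with zero conditional mean
    when the per-bin spike probability equals ``rho*dt``.

    ``form='discrete_exact'`` returns the derivative of the exact Bernoulli
    log-pmf instead, ``(X * a/(e^a - 1) - (1-X) * a) / delta_u`` with
    ``a = rho*dt``, whose conditional mean is exactly zero under the
    ``1 - exp(-a)`` sampler.

    Returns the full ``(n_neurons, n_bins)`` matrix when ``neuron`` and
    ``t_bin`` are omitted.
    """
    which = which.upper()
    rho = trace.rho_g if which == "G" else trace.rho_q
    if rho is None:
        raise ValueError(f"trace does not record the {which}-side intensities")
    p = trace.params
    X = trace.raster.spikes.astype(float)
    a = rho * p.dt
    if form == "continuous_limit":
        pf = (X - a) / p.delta_u
    elif form == "discrete_exact":
        with np.errstate(over="ignore"):
            spike_coef = np.where(a > 0, a / np.expm1(a), 1.0)
        pf = (X * spike_coef - (1.0 - X) * a) / p.delta_u
    else:
        raise ValueError(f"unknown form {form!r}")
    if neuron is not None and t_bin is not None:
        return float(pf[neuron, t_bin])
    if neuron is not None:
        return pf[neuron]
    return pf


def _accumulate(pf: np.ndarray, phi: np.ndarray, window=None) -> np.ndarray:
    """Sum over bins of outer(post_factor_t, phi_t): the batch gradient."""
    if window is not None:
        sl = slice(window[0], window[1]) if not isinstance(window, slice) else window
        pf, phi = pf[:, sl], phi[:, sl]
    if pf.shape[1] == 0:
        raise ValueError("empty window")
    return pf @ phi.T


def fully_observed_gradient(trace: NetworkTrace, window=None,
                            form: str = "continuous_limit") -> np.ndarray:
    """Gradient of the complete-data log-likelihood w.r.t. the generative
    weights: ``grad_ij = sum_t post_factor_i(t) * phi_j(t)`` with zero
    diagonal.  For a network without hidden neurons ascent on this gradient
    solves a convex maximum-likelihood problem."""
    grad = _accumulate(post_factor(trace, "G", form=form), trace.phi, window)
    np.fill_diagonal(grad, 0.0)
    return grad


def _q_score_sum(trace: NetworkTrace, form: str, window=None) -> np.ndarray:
    """Batch sum of the Q-score outer products, masked to the Q support
    (hidden postsynaptic rows, zero diagonal)."""
    s = _accumulate(post_factor(trace, "Q", form=form), trace.phi, window)
    np.fill_diagonal(s, 0.0)
    s[: trace.n_visible, :] = 0.0
    return s


def naive_batch_update(trace: NetworkTrace, f_hat: float, cfg: LearnerConfig):
    """Naive batch updates: Hebbian for G, free-energy-modulated score
    estimator for Q.  Returns ``(dw_g, dw_q)``."""
    dw_g = cfg.mu_g * fully_observed_gradient(trace, form=cfg.form)
    dw_q = -cfg.mu_q * f_hat * _q_score_sum(trace, cfg.form)
    return dw_g, dw_q


def variance_reduced_update(trace: NetworkTrace, f_hat: float, baseline: float,
                            cfg: LearnerConfig):
    """As :func:`naive_batch_update` with the free-energy error signal
    ``e(T) = F(T) - baseline`` as the modulator.  The baseline is spike-
    independent, so the expected update is unchanged."""
    return naive_batch_update(trace, f_hat - baseline, cfg)


def online_step(traces: HebbianTraces, trace: NetworkTrace, t_bin: int,
                tracker: FreeEnergyTracker, cfg: LearnerConfig):
    """One bin of the online rule (functional form, on a recorded trace).

    Updates the Hebbian traces toward the instantaneous pre/post outer
    product, advances the novelty tracker with the full instantaneous free
    energy, and returns per-bin weight increments: a two-factor Hebbian
    update for the generative weights and a three-factor update
    ``-mu_q * e_N * H_q * dt`` for the recognition weights.

    Returns ``(traces', dw_g, dw_q, tracker')``.
    """
    if trace.mode == "generate":
        raise ValueError("online learning requires a learn-mode trace")
    p = trace.params
    traces = traces.copy()
    tracker = tracker.copy()
    phi_t = trace.phi[:, t_bin]
    pf_g = post_factor(trace, "G", form=cfg.form)[:, t_bin]
    pf_q = post_factor(trace, "Q", form=cfg.form)[:, t_bin]
    alpha = p.dt / cfg.tau_g
    outer_g = np.outer(pf_g, phi_t)
    outer_q = np.outer(pf_q, phi_t)
    np.fill_diagonal(outer_g, 0.0)
    np.fill_diagonal(outer_q, 0.0)
    outer_q[: trace.n_visible, :] = 0.0
    traces.h_g += alpha * (outer_g - traces.h_g)
    traces.h_q += alpha * (outer_q - traces.h_q)
    f_t = instantaneous_free_energy(trace, t_bin, variant="full", form=cfg.form)
    e_n = tracker.update(f_t, p.dt)
    dw_g = cfg.mu_g * traces.h_g * p.dt
    dw_q = -cfg.mu_q * e_n * traces.h_q * p.dt
    return traces, dw_g, dw_q, tracker


def simplified_step(traces: HebbianTraces, trace: NetworkTrace, t_bin: int,
                    tracker: FreeEnergyTracker, cfg: LearnerConfig):
    """One bin of the merged-network rule: a single weight set, hidden
    neurons driven by the generative weights, novelty from the visible-only
    free energy.  Synapses onto visible neurons follow the two-factor rule;
    synapses onto hidden neurons follow the three-factor rule.

    Returns ``(traces', dw, tracker')`` where ``dw`` is the combined update
    of the single weight set.
    """
    if trace.mode == "generate":
        raise ValueError("online learning requires a learn-mode trace")
    p = trace.params
    nv = trace.n_visible
    traces = traces.copy()
    tracker = tracker.copy()
    phi_t = trace.phi[:, t_bin]
    pf = post_factor(trace, "G", form=cfg.form)[:, t_bin]
    outer = np.outer(pf, phi_t)
    np.fill_diagonal(outer, 0.0)
    traces.h_g += (p.dt / cfg.tau_g) * (outer - traces.h_g)
    f_t = instantaneous_free_energy(trace, t_bin, variant="simplified", form=cfg.form)
    e_n = tracker.update(f_t, p.dt)
    dw = np.empty_like(traces.h_g)
    dw[:nv] = cfg.mu_g * traces.h_g[:nv] * p.dt
    dw[nv:] = -cfg.mu_q * e_n * traces.h_g[nv:] * p.dt
    return traces, dw, tracker


def run_online_batch(net: DualNetwork, clamp, traces: HebbianTraces,
                     tracker: FreeEnergyTracker, cfg: LearnerConfig,
                     rng: np.random.Generator,
                     state: Optional[SimulationState] = None,
                     learn: bool = True,
                     variant: Optional[str] = None):
    """Fused simulate-and-learn loop over one clamped batch.

    The online rules update the weights at every bin, so the dynamics and
    the learning cannot be separated into a simulate-then-update pass; this
    driver inlines both.  ``net.w_g``/``net.w_q`` are modified in place
    when ``learn`` is true.  For ``variant='simplified'`` the hidden
    neurons are driven by the generative weights (tied proposal) and the
    single weight set receives the combined update.

    Returns a dict with the per-bin free-energy series, the novelty series
    and the final carry-over state.
    """
    variant = variant or cfg.variant
    if variant not in ("online", "simplified"):
        raise ValueError("variant must be 'online' or 'simplified'")
    p = net.params
    n, nv = net.n_neurons, net.n_visible
    clamp_arr = clamp.spikes if isinstance(clamp, SpikeRaster) else np.asarray(clamp)
    nb = clamp_arr.shape[1]
    if clamp_arr.shape[0] != nv:
        raise ValueError("clamp height must equal n_visible")
    phi = np.zeros(n) if state is None else state.phi.copy()
    eta = np.zeros(n) if state is None else state.eta.copy()
    log_rho0 = np.log(p.rho0)
    f_series = np.empty(nb)
    e_series = np.empty(nb)
    alpha = p.dt / cfg.tau_g
    x_t = np.empty(n)
    for t in range(nb):
        phi = phi * p.phi_decay
        eta = eta * p.eta_decay
        u_g = net.w_g @ phi + eta
        rho_g = firing_intensity(u_g, p)
        if variant == "simplified":
            u_h, rho_h = u_g[nv:], rho_g[nv:]
        else:
            u_q_h = net.w_q[nv:] @ phi + eta[nv:]
            rho_h = firing_intensity(u_q_h, p)
        x_t[:nv] = clamp_arr[:, t]
        x_t[nv:] = rng.random(n - nv) < -np.expm1(-p.dt * rho_h)

        pf_g = (x_t - rho_g * p.dt) / p.delta_u
        log_rho_g = log_rho0 + (u_g - p.theta) / p.delta_u
        f_vis = -(x_t[:nv] * log_rho_g[:nv] - rho_g[:nv] * p.dt).sum()
        if variant == "simplified":
            f_t = f_vis
            outer = np.outer(pf_g, phi)
            np.fill_diagonal(outer, 0.0)
            traces.h_g += alpha * (outer - traces.h_g)
            e_n = tracker.update(f_t, p.dt)
            if learn:
                net.w_g[:nv] += cfg.mu_g * traces.h_g[:nv] * p.dt
                net.w_g[nv:] += -cfg.mu_q * e_n * traces.h_g[nv:] * p.dt
                np.fill_diagonal(net.w_g, 0.0)
        else:
            log_rho_h = log_rho0 + (u_q_h - p.theta) / p.delta_u
            f_hid = -(x_t[nv:] * log_rho_g[nv:] - rho_g[nv:] * p.dt).sum() \
                + (x_t[nv:] * log_rho_h - rho_h * p.dt).sum()
            f_t = f_vis + f_hid
            pf_q_h = (x_t[nv:] - rho_h * p.dt) / p.delta_u
            outer_g = np.outer(pf_g, phi)
            np.fill_diagonal(outer_g, 0.0)
            traces.h_g += alpha * (outer_g - traces.h_g)
            outer_q = np.outer(pf_q_h, phi)
            traces.h_q[nv:] += alpha * (outer_q - traces.h_q[nv:])
            traces.h_q[nv + np.arange(n - nv), nv + np.arange(n - nv)] = 0.0
            e_n = tracker.update(f_t, p.dt)
            if learn:
                net.w_g += cfg.mu_g * traces.h_g * p.dt
                net.w_q[nv:] += -cfg.mu_q * e_n * traces.h_q[nv:] * p.dt
                np.fill_diagonal(net.w_g, 0.0)
                np.fill_diagonal(net.w_q, 0.0)
        f_series[t] = f_t
        e_series[t] = e_n
        phi = phi + x_t
        eta = eta - p.eta0 * x_t
    return {
        "f_series": f_series,
        "e_series": e_series,
        "state": SimulationState(phi=phi.copy(), eta=eta.copy()),
    }


def variance_scaling_experiment(n_hidden_list, n_batches: int = 500,
                                cfg: Optional[LearnerConfig] = None,
                                seed: Optional[int] = None,
                                n_visible: Optional[int] = None,
                                batch_bins: int = 200,
                                visible_rate_khz: float = 0.05,
                                weight_sd: Optional[float] = None,
                                warmup: int = 20):
    """Empirical scaling of the Q-update variance with network size.

    For each hidden count ``N``: fix random weights (no learning), draw
    ``n_batches`` independent Poisson visible batches, run the recognition
    network clamped to each, and record the naive and baseline-removed
    update of one fixed hidden synapse.  The baseline is an exponential
    moving average of the free energy over *previous* batches, so it is
    independent of the current batch.  Returns ``(table, slope_naive,
    slope_vr)`` where the slopes are log-log fits of variance against N.

    By default the visible count scales together with the hidden count
    (``n_visible=None`` means ``n_visible = N``): the modulator of the
    naive update is the windowed free energy, a sum over *all* neurons, so
    its mean grows with the network size and the naive update variance
    grows roughly quadratically, versus roughly linearly once the baseline
    removes the mean.  Pass an integer to pin the visible count instead.

    The quadratic-versus-linear prediction assumes weak coupling: each
    neuron contributes a free-energy term whose variance does not itself
    grow with the network.  With a fixed weight sd the summed synaptic
    input fluctuation grows with the in-degree and breaks that assumption,
    so by default the fixed random weights scale as
    ``0.04 / sqrt(n_neurons)`` (``weight_sd=None``), keeping the
    per-neuron input variance constant across N; pass an explicit sd to
    override.
    """
    import pandas as pd

    from .core_dynamics import run_network

    n_hidden_list = list(n_hidden_list)
    if len(n_hidden_list) < 2:
        raise ValueError("need at least two hidden-layer sizes")
    cfg = cfg or LearnerConfig()
    if n_batches <= warmup + 2:
        raise ValueError("n_batches must exceed the baseline warmup")
    rng = np.random.default_rng(seed)
    rows = []
    for n_hidden in n_hidden_list:
        nv = n_hidden if n_visible is None else n_visible
        sd = 0.04 / np.sqrt(nv + n_hidden) if weight_sd is None else weight_sd
        net = DualNetwork.random_init(nv, n_hidden, weight_sd=sd,
                                      seed=rng.integers(2**31))
        p_spike = -np.expm1(-net.params.dt * visible_rate_khz)
        syn = (nv, 0)  # fixed hidden-postsynaptic synapse
        f_hats = np.empty(n_batches)
        scores = np.empty(n_batches)
        for b in range(n_batches):
            clamp = (rng.random((nv, batch_bins)) < p_spike).astype(np.uint8)
            trace = run_network(net, "learn", batch_bins, clamp=clamp, rng_seed=rng)
            f_hats[b] = windowed_free_energy(trace, form=cfg.form)
            scores[b] = _q_score_sum(trace, cfg.form)[syn]
        baselines = np.empty(n_batches)
        bl = f_hats[0]
        for b in range(n_batches):
            baselines[b] = bl
            bl += cfg.baseline_decay * (f_hats[b] - bl)
        naive = -cfg.mu_q * f_hats[warmup:] * scores[warmup:]
        vr = -cfg.mu_q * (f_hats[warmup:] - baselines[warmup:]) * scores[warmup:]
        rows.append({"n_hidden": n_hidden,
                     "var_naive": float(np.var(naive, ddof=1)),
                     "var_vr": float(np.var(vr, ddof=1)),
                     "mean_f_hat": float(f_hats[warmup:].mean())})
    table = pd.DataFrame(rows)
    logn = np.log(table["n_hidden"].to_numpy(dtype=float))
    slope_naive = float(np.polyfit(logn, np.log(table["var_naive"]), 1)[0])
    slope_vr = float(np.polyfit(logn, np.log(table["var_vr"]), 1)[0])
    return table, slope_naive, slope_vr
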