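"""Discrete-time dynamics of a stochastic spiking network.

Neurons follow a Spike Response Model with escape noise: the membrane
potential of neuron ``i`` is a weighted sum of exponentially filtered
presynaptic spike trains (EPSP traces ``phi``) plus a spike-triggered
adaptation potential ``eta``, and spikes are emitted by a conditional
Poisson process with exponential escape rate

    rho_i(t) = rho0 * exp[(u_i(t) - theta) / delta_u].

Time is discretized in bins of width ``dt``; the probability of a spike in
a bin is ``1 - exp(-rho * dt)``, which enforces at most one spike per bin.

The network carries two synapse sets on the same neurons: the generative
weights ``w_g`` define the joint model over all spike trains, and the
recognition weights ``w_q`` (structurally zero onto visible neurons) define
an approximate posterior over hidden spikes given clamped visible data.

Conventions
-----------
Arrays are indexed ``(neuron, time_bin)``; weight matrices are
``(postsynaptic, presynaptic)``.  Within a bin, potentials and intensities
are computed from traces reflecting spikes up to the *previous* bin, the
bin's spikes are then sampled, and traces are updated afterwards, so a
spike can never influence its own emission probability.  The recorded
``phi[:, t]`` and ``eta[:, t]`` are the trace values *entering* bin ``t``
— the exact convolutions ``sum_f exp(-(t - t_f)/tau)`` over spikes
strictly before ``t`` — which makes ``u[:, t] == w @ phi[:, t] +
eta[:, t]`` hold bin by bin while keeping the dynamics causal.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "NeuronParams",
    "SpikeRaster",
    "DualNetwork",
    "NetworkTrace",
    "SimulationState",
    "decay_and_increment",
    "adaptation_step",
    "membrane_potential",
    "firing_intensity",
    "log_firing_intensity",
    "spike_probability",
    "run_network",
    "trace_from_raster",
]

_EXP_CLIP = 500.0  # exponent clip in the escape rate, overflow guard only


@dataclass(frozen=True)
class NeuronParams:
    """Physical constants of the stochastic SRM neuron.

    Defaults are the values used throughout the simulations: 1 ms bins,
    10 ms membrane and adaptation time constants, 0.1 mV adaptation
    strength, 1 kHz rate scale, 0 mV threshold and 1 mV firing sensitivity.
    """

    dt: float = 1.0          # time-bin width, ms
    tau: float = 10.0        # membrane/EPSP time constant, ms
    eta0: float = 0.1        # adaptation potential strength, mV
    tau_adapt: float = 10.0  # adaptation time constant, ms
    rho0: float = 1.0        # firing-rate scale, kHz
    theta: float = 0.0       # firing threshold, mV
    delta_u: float = 1.0     # firing sensitivity, mV

    def __post_init__(self) -> None:
        for name in ("dt", "tau", "tau_adapt", "rho0", "delta_u"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"NeuronParams.{name} must be strictly positive")
        if self.eta0 < 0:
            raise ValueError("NeuronParams.eta0 must be non-negative")

    @property
    def phi_decay(self) -> float:
        return float(np.exp(-self.dt / self.tau))

    @property
    def eta_decay(self) -> float:
        return float(np.exp(-self.dt / self.tau_adapt))

    def to_json(self) -> str:
        return json.dumps(
            {k: getattr(self, k) for k in
             ("dt", "tau", "eta0", "tau_adapt", "rho0", "theta", "delta_u")},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NeuronParams":
        return cls(**json.loads(text))


def decay_and_increment(trace_value: float, n_spikes: int, dt: float, tau: float) -> float:
    """One-bin exact propagation of the exponential filter.

    Returns ``trace_value * exp(-dt/tau) + n_spikes``: the exact solution of
    ``tau * dphi/dt = -phi`` between spikes, with a unit increment at a spike.
    """
    if dt <= 0 or tau <= 0:
        raise ValueError("dt and tau must be strictly positive")
    if n_spikes not in (0, 1):
        raise ValueError("at most one spike per bin")
    return trace_value * np.exp(-dt / tau) + n_spikes


def adaptation_step(eta_value: float, own_spike: int, params: NeuronParams) -> float:
    """One-bin update of the (non-positive) adaptation potential, mV."""
    if own_spike not in (0, 1):
        raise ValueError("at most one spike per bin")
    return eta_value * params.eta_decay - params.eta0 * own_spike


def membrane_potential(weights_row: np.ndarray, phi: np.ndarray, eta: float) -> float:
    """Membrane potential: weighted EPSP traces plus adaptation, mV."""
    weights_row = np.asarray(weights_row, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if weights_row.shape != phi.shape:
        raise ValueError("weights_row and phi must have equal length")
    return float(weights_row @ phi + eta)


def firing_intensity(u, params: NeuronParams):
    """Exponential escape rate ``rho0 * exp[(u - theta)/delta_u]``, kHz."""
    z = np.clip((np.asarray(u, dtype=float) - params.theta) / params.delta_u,
                -_EXP_CLIP, _EXP_CLIP)
    return params.rho0 * np.exp(z)


def log_firing_intensity(u, params: NeuronParams):
    """log rho computed as log(rho0) + (u - theta)/delta_u (never exp-then-log)."""
    return np.log(params.rho0) + (np.asarray(u, dtype=float) - params.theta) / params.delta_u


def spike_probability(rho, dt: float):
    """Probability of at least (hence exactly) one spike in a bin: 1 - exp(-rho*dt)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    return -np.expm1(-dt * rho)


@dataclass
class SpikeRaster:
    """Binary spike raster: entry (i, t) is 1 iff neuron i spiked in bin t.

    Bins are half-open intervals ``[t, t+dt)`` with 0-based indices.
    """

    spikes: np.ndarray
    dt: float = 1.0
    neuron_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be a (neuron, time_bin) matrix")
        if not np.isin(self.spikes, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.spikes = self.spikes.astype(np.uint8)
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.spikes.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if self.neuron_ids.shape != (self.spikes.shape[0],):
                raise ValueError("neuron_ids length must match raster height")

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    def to_events(self) -> str:
        """Event-list TSV (header + neuron_id, time_ms rows), bin-aligned times."""
        buf = io.StringIO()
        buf.write(f"# n_neurons={self.n_neurons}\tn_bins={self.n_bins}\tdt={self.dt}\n")
        buf.write("neuron_id\ttime_ms\n")
        rows, cols = np.nonzero(self.spikes)
        for i, t in zip(rows, cols):
            buf.write(f"{int(self.neuron_ids[i])}\t{t * self.dt}\n")
        return buf.getvalue()

    @classmethod
    def from_events(cls, text: str) -> "SpikeRaster":
        lines = text.strip().splitlines()
        meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split("\t"))
        n_neurons, n_bins, dt = int(meta["n_neurons"]), int(meta["n_bins"]), float(meta["dt"])
        spikes = np.zeros((n_neurons, n_bins), dtype=np.uint8)
        for line in lines[2:]:
            nid, t_ms = line.split("\t")
            spikes[int(nid), int(round(float(t_ms) / dt))] = 1
        return cls(spikes=spikes, dt=dt)

    def save_npz(self, path) -> None:
        np.savez_compressed(path, spikes=self.spikes, dt=self.dt,
                            neuron_ids=self.neuron_ids)

    @classmethod
    def load_npz(cls, path) -> "SpikeRaster":
        with np.load(path) as f:
            return cls(spikes=f["spikes"], dt=float(f["dt"]), neuron_ids=f["neuron_ids"])


@dataclass
class DualNetwork:
    """Neuron partition plus the two synaptic weight matrices.

    Neurons ``0 .. n_visible-1`` are visible, the rest hidden.  ``w_g``
    parameterizes the generative model; ``w_q`` the recognition network,
    whose rows for visible postsynaptic neurons are structurally zero
    (the recognition topology excludes connections onto visible neurons).
    Diagonals of both matrices are zero: self-influence is carried by the
    adaptation potential, never by an explicit self-synapse.
    """

    n_visible: int
    n_hidden: int
    params: NeuronParams = field(default_factory=NeuronParams)
    w_g: Optional[np.ndarray] = None
    w_q: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_visible < 1 or self.n_hidden < 0:
            raise ValueError("need n_visible >= 1 and n_hidden >= 0")
        n = self.n_neurons
        if self.w_g is None:
            self.w_g = np.zeros((n, n))
        if self.w_q is None:
            self.w_q = np.zeros((n, n))
        self.w_g = np.asarray(self.w_g, dtype=float)
        self.w_q = np.asarray(self.w_q, dtype=float)
        for name, w in (("w_g", self.w_g), ("w_q", self.w_q)):
            if w.shape != (n, n):
                raise ValueError(f"{name} must be ({n}, {n})")
            if not np.isfinite(w).all():
                raise ValueError(f"{name} must be finite")
            if np.any(np.diag(w) != 0):
                raise ValueError(f"{name} diagonal must be zero")
        if np.any(self.w_q[: self.n_visible, :] != 0):
            raise ValueError("w_q rows for visible postsynaptic neurons must be zero")

    @property
    def n_neurons(self) -> int:
        return self.n_visible + self.n_hidden

    @property
    def visible(self) -> np.ndarray:
        return np.arange(self.n_visible)

    @property
    def hidden(self) -> np.ndarray:
        return np.arange(self.n_visible, self.n_neurons)

    def structural_mask(self, which: str) -> np.ndarray:
        """Boolean matrix of structurally allowed synapses for 'G' or 'Q'."""
        n = self.n_neurons
        mask = ~np.eye(n, dtype=bool)
        if which.upper() == "Q":
            mask[: self.n_visible, :] = False
        elif which.upper() != "G":
            raise ValueError("which must be 'G' or 'Q'")
        return mask

    @classmethod
    def random_init(cls, n_visible: int, n_hidden: int,
                    params: Optional[NeuronParams] = None,
                    weight_sd: float = 0.01,
                    seed: Optional[int] = None) -> "DualNetwork":
        """Gaussian initial weights, mean 0 and sd 0.01 by default."""
        rng = np.random.default_rng(seed)
        n = n_visible + n_hidden
        net = cls(n_visible, n_hidden, params or NeuronParams())
        w_g = rng.normal(0.0, weight_sd, (n, n))
        w_q = rng.normal(0.0, weight_sd, (n, n))
        np.fill_diagonal(w_g, 0.0)
        np.fill_diagonal(w_q, 0.0)
        w_q[:n_visible, :] = 0.0
        net.w_g, net.w_q = w_g, w_q
        return net

    def copy(self) -> "DualNetwork":
        return DualNetwork(self.n_visible, self.n_hidden, self.params,
                           self.w_g.copy(), self.w_q.copy())


@dataclass
class SimulationState:
    """Carry-over trace state between consecutive windows of one trajectory."""

    phi: np.ndarray
    eta: np.ndarray

    @classmethod
    def zeros(cls, n_neurons: int) -> "SimulationState":
        return cls(phi=np.zeros(n_neurons), eta=np.zeros(n_neurons))


@dataclass
class NetworkTrace:
    """Recorded time series of one simulated window.

    ``phi[:, t]`` / ``eta[:, t]`` are the trace values entering bin ``t``;
    ``u_*`` and ``rho_*`` are the potentials and intensities used in bin
    ``t``, so ``u = w @ phi + eta`` holds column by column.  Which of the
    G-/Q-side arrays are present depends on the simulation mode.
    """

    raster: SpikeRaster
    phi: np.ndarray
    eta: np.ndarray
    u_g: Optional[np.ndarray] = None
    u_q: Optional[np.ndarray] = None
    rho_g: Optional[np.ndarray] = None
    rho_q: Optional[np.ndarray] = None
    params: NeuronParams = field(default_factory=NeuronParams)
    n_visible: int = 0
    mode: str = "generate"
    final_state: Optional[SimulationState] = None

    @property
    def n_bins(self) -> int:
        return self.raster.n_bins

    @property
    def n_neurons(self) -> int:
        return self.raster.n_neurons


def _simulate(net: DualNetwork, mode: str, duration_bins: int,
              clamp: Optional[np.ndarray], rng: np.random.Generator,
              state: Optional[SimulationState]) -> NetworkTrace:
    p = net.params
    n = net.n_neurons
    nv = net.n_visible
    need_g = mode in ("generate", "learn")
    need_q = mode in ("infer", "learn")

    if state is None:
        phi = np.zeros(n)
        eta = np.zeros(n)
    else:
        phi = state.phi.copy()
        eta = state.eta.copy()

    X = np.zeros((n, duration_bins), dtype=np.uint8)
    phi_rec = np.empty((n, duration_bins))
    eta_rec = np.empty((n, duration_bins))
    u_g = np.empty((n, duration_bins)) if need_g else None
    u_q = np.empty((n, duration_bins)) if need_q else None

    phi_decay, eta_decay = p.phi_decay, p.eta_decay
    for t in range(duration_bins):
        phi *= phi_decay
        eta *= eta_decay
        phi_rec[:, t] = phi
        eta_rec[:, t] = eta
        if need_g:
            u_g[:, t] = net.w_g @ phi + eta
        if need_q:
            u_q[:, t] = net.w_q @ phi + eta
        if mode == "generate":
            rho_samp = firing_intensity(u_g[:, t], p)
            x_t = (rng.random(n) < -np.expm1(-p.dt * rho_samp)).astype(np.uint8)
        else:
            x_t = np.empty(n, dtype=np.uint8)
            x_t[:nv] = clamp[:, t]
            if n > nv:
                rho_h = firing_intensity(u_q[nv:, t], p)
                x_t[nv:] = rng.random(n - nv) < -np.expm1(-p.dt * rho_h)
        X[:, t] = x_t
        phi += x_t
        eta -= p.eta0 * x_t

    rho_g = firing_intensity(u_g, p) if need_g else None
    rho_q = firing_intensity(u_q, p) if need_q else None
    return NetworkTrace(
        raster=SpikeRaster(X, dt=p.dt), phi=phi_rec, eta=eta_rec,
        u_g=u_g, u_q=u_q, rho_g=rho_g, rho_q=rho_q,
        params=p, n_visible=nv, mode=mode,
        final_state=SimulationState(phi=phi, eta=eta),
    )


def run_network(net: DualNetwork, mode: str, duration_bins: int,
                clamp: Optional[SpikeRaster] = None,
                rng_seed=None,
                state: Optional[SimulationState] = None) -> NetworkTrace:
    """Simulate the network for ``duration_bins`` bins.

    Parameters
    ----------
    mode:
        ``"generate"`` — all neurons sampled from the generative weights;
        a sample from the generative model.  ``"infer"`` — visible neurons
        clamped to ``clamp``, hidden neurons sampled from the recognition
        weights; an approximate posterior sample.  ``"learn"`` — as infer,
        but the generative-side potentials and intensities are additionally
        evaluated on the same spike history (as required by the gradients).
    clamp:
        Visible raster, shape ``(n_visible, duration_bins)``; required for
        infer/learn, forbidden for generate.
    rng_seed:
        Seed or ``numpy.random.Generator``; identical seeds give identical
        traces.
    state:
        Optional carry-over of ``phi``/``eta`` from a previous window
        (default: start from zero traces).
    """
    if mode not in ("generate", "infer", "learn"):
        raise ValueError(f"unknown mode {mode!r}")
    if duration_bins <= 0:
        raise ValueError("duration_bins must be positive")
    if mode == "generate":
        if clamp is not None:
            raise ValueError("generate mode forbids a clamp")
        clamp_arr = None
    else:
        if clamp is None:
            raise ValueError(f"{mode} mode requires a clamp over visible neurons")
        clamp_arr = clamp.spikes if isinstance(clamp, SpikeRaster) else np.asarray(clamp)
        if clamp_arr.shape != (net.n_visible, duration_bins):
            raise ValueError(
                f"clamp must have shape ({net.n_visible}, {duration_bins}), "
                f"got {clamp_arr.shape}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    return _simulate(net, mode, duration_bins, clamp_arr, rng, state)


def trace_from_raster(net: DualNetwork, raster: SpikeRaster,
                      state: Optional[SimulationState] = None) -> NetworkTrace:
    """Deterministically evaluate traces, potentials and intensities for a
    *given* full raster (no sampling); used by gradients and the
    enumeration oracle.  Both G- and Q-side quantities are recorded."""
    p = net.params
    X = raster.spikes
    n, nb = X.shape
    if n != net.n_neurons:
        raise ValueError("raster height must equal the network size")
    phi = np.zeros(n) if state is None else state.phi.copy()
    eta = np.zeros(n) if state is None else state.eta.copy()
    phi_rec = np.empty((n, nb))
    eta_rec = np.empty((n, nb))
    for t in range(nb):
        phi = phi * p.phi_decay
        eta = eta * p.eta_decay
        phi_rec[:, t] = phi
        eta_rec[:, t] = eta
        phi = phi + X[:, t]
        eta = eta - p.eta0 * X[:, t]
    u_g = net.w_g @ phi_rec + eta_rec
    u_q = net.w_q @ phi_rec + eta_rec
    return NetworkTrace(
        raster=raster, phi=phi_rec, eta=eta_rec,
        u_g=u_g, u_q=u_q,
        rho_g=firing_intensity(u_g, p), rho_q=firing_intensity(u_q, p),
        params=p, n_visible=net.n_visible, mode="learn",
        final_state=SimulationState(phi=phi, eta=eta),
    )
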