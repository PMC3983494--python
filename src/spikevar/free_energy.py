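"""Point-process log-likelihoods, the free energy, and the novelty signal.

Two per-bin likelihood forms are supported:

``continuous_limit``
    ``X log(rho) - rho*dt`` — the small-bin limit of the point-process
    likelihood, used by the learning rules.

``discrete_exact``
    ``X log(1 - exp(-rho*dt)) - (1 - X) rho*dt`` — the exact log-pmf of the
    Bernoulli sampler that emits a spike with probability
    ``1 - exp(-rho*dt)``.  This form is a proper probability mass function
    over binary rasters (it sums to one) and is the one used by the
    enumeration oracle, so that exactness tests are exact.

The free energy of a window is ``F = -L_G + L_Q`` where ``L_G`` is the
complete-data log-likelihood of all neurons under the generative weights
and ``L_Q`` is the log-probability of the hidden spikes under the
recognition weights.  Averaged over the recognition distribution it upper
bounds the negative log-likelihood of the visible data; the gap is the
KL divergence from the recognition distribution to the true posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_dynamics import NetworkTrace, log_firing_intensity

__all__ = [
    "LIKELIHOOD_FORMS",
    "per_bin_log_likelihood",
    "complete_log_likelihood",
    "instantaneous_free_energy",
    "windowed_free_energy",
    "FreeEnergyTracker",
    "novelty_trace_tsv",
]

LIKELIHOOD_FORMS = ("continuous_limit", "discrete_exact")


def _check_form(form: str) -> None:
    if form not in LIKELIHOOD_FORMS:
        raise ValueError(f"form must be one of {LIKELIHOOD_FORMS}, got {form!r}")


def per_bin_log_likelihood(x: np.ndarray, log_rho: np.ndarray, rho: np.ndarray,
                           dt: float, form: str = "continuous_limit") -> np.ndarray:
    """Elementwise per-bin log-likelihood terms (nats)."""
    _check_form(form)
    x = np.asarray(x, dtype=float)
    a = rho * dt
    if form == "continuous_limit":
        return x * log_rho - a
    # log(1 - e^{-a}) computed stably via log(-expm1(-a))
    with np.errstate(divide="ignore"):
        log_p_spike = np.log(-np.expm1(-a))
    return x * log_p_spike - (1.0 - x) * a


def complete_log_likelihood(trace: NetworkTrace, which: str = "G",
                            neuron_subset=None,
                            form: str = "continuous_limit") -> float:
    """Complete-data log-likelihood of the raster in ``trace`` (nats).

    ``which='G'`` evaluates the generative model over any subset of neurons
    (default: all).  ``which='Q'`` evaluates the recognition distribution,
    which is defined over hidden spikes only; requesting visible neurons is
    a contract error.
    """
    _check_form(form)
    which = which.upper()
    p = trace.params
    if which == "G":
        u, rho = trace.u_g, trace.rho_g
        default = np.arange(trace.n_neurons)
    elif which == "Q":
        u, rho = trace.u_q, trace.rho_q
        default = np.arange(trace.n_visible, trace.n_neurons)
    else:
        raise ValueError("which must be 'G' or 'Q'")
    if u is None:
        raise ValueError(f"trace does not record the {which}-side intensities")
    subset = np.asarray(default if neuron_subset is None else list(neuron_subset))
    if subset.size == 0:
        raise ValueError("neuron_subset must be non-empty")
    if which == "Q" and np.any(subset < trace.n_visible):
        raise ValueError("the recognition distribution is over hidden neurons only")
    log_rho = log_firing_intensity(u[subset], p)
    terms = per_bin_log_likelihood(trace.raster.spikes[subset], log_rho,
                                   rho[subset], p.dt, form)
    return float(terms.sum())


def _fe_terms(trace: NetworkTrace, variant: str, form: str) -> np.ndarray:
    """Per-bin instantaneous free energy, shape (n_bins,)."""
    _check_form(form)
    if trace.mode == "generate":
        raise ValueError("free energy requires a learn-mode trace")
    p = trace.params
    X = trace.raster.spikes.astype(float)
    nv = trace.n_visible
    if variant == "simplified":
        log_rho = log_firing_intensity(trace.u_g[:nv], p)
        terms = per_bin_log_likelihood(X[:nv], log_rho, trace.rho_g[:nv], p.dt, form)
        return -terms.sum(axis=0)
    if variant != "full":
        raise ValueError("variant must be 'full' or 'simplified'")
    if trace.u_g is None or trace.u_q is None:
        raise ValueError("full free energy requires both G- and Q-side intensities")
    lg = per_bin_log_likelihood(X, log_firing_intensity(trace.u_g, p),
                                trace.rho_g, p.dt, form).sum(axis=0)
    lq = per_bin_log_likelihood(X[nv:], log_firing_intensity(trace.u_q[nv:], p),
                                trace.rho_q[nv:], p.dt, form).sum(axis=0)
    return -lg + lq


def instantaneous_free_energy(trace: NetworkTrace, t_bin: Optional[int] = None,
                              variant: str = "full",
                              form: str = "continuous_limit"):
    """Instantaneous free energy F_t (nats per bin).

    ``variant='full'`` uses all neurons under G and the hidden neurons under
    Q; ``variant='simplified'`` sums over the visible neurons only (the
    merged-network objective).  With ``t_bin=None`` the whole per-bin series
    is returned.
    """
    series = _fe_terms(trace, variant, form)
    return series if t_bin is None else float(series[t_bin])


def windowed_free_energy(trace: NetworkTrace, variant: str = "full",
                         form: str = "continuous_limit") -> float:
    """Point estimate F(T): the sum of F_t over the window (nats)."""
    return float(_fe_terms(trace, variant, form).sum())


@dataclass
class FreeEnergyTracker:
    """Two-stage moving averages of the instantaneous free energy.

    ``fast_avg`` low-passes F_t with time constant ``tau_g``; the
    ``slow_baseline`` low-passes the fast average with the longer time
    constant ``tau_baseline``, so the baseline's effective time scale
    depends on both constants.  The novelty signal is their difference
    ``e_N = fast_avg - slow_baseline``: a transient surprise measure
    relative to the slow background surprise level.

    On the first update both averages warm-start at the observed value
    (unless explicit initial values are supplied), so the signal measures
    novelty relative to experience rather than relative to an arbitrary
    zero initial state.
    """

    tau_g: float = 10.0
    tau_baseline: float = 100.0
    fast_avg: Optional[float] = None
    slow_baseline: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tau_g <= 0 or self.tau_baseline <= 0:
            raise ValueError("time constants must be strictly positive")

    @property
    def e_n(self) -> float:
        if self.fast_avg is None:
            return 0.0
        return self.fast_avg - self.slow_baseline

    def update(self, f_instant: float, dt: float) -> float:
        """Advance both averages one bin; returns the novelty signal e_N."""
        if self.fast_avg is None:
            self.fast_avg = f_instant
        if self.slow_baseline is None:
            self.slow_baseline = self.fast_avg
        self.fast_avg += (dt / self.tau_g) * (f_instant - self.fast_avg)
        self.slow_baseline += (dt / self.tau_baseline) * (self.fast_avg - self.slow_baseline)
        return self.e_n

    def copy(self) -> "FreeEnergyTracker":
        return FreeEnergyTracker(self.tau_g, self.tau_baseline,
                                 self.fast_avg, self.slow_baseline)


def update_novelty(tracker: FreeEnergyTracker, f_instant: float, dt: float):
    """Functional wrapper: returns (updated tracker copy, e_N)."""
    t2 = tracker.copy()
    e_n = t2.update(f_instant, dt)
    return t2, e_n


def novelty_trace_tsv(f_series: np.ndarray, tracker: FreeEnergyTracker,
                      dt: float) -> str:
    """Run a fresh copy of ``tracker`` over ``f_series`` and format the
    result as a TSV time series (bin, time_ms, f_instant, fast, slow, e_n)."""
    trk = tracker.copy()
    lines = ["bin\ttime_ms\tf_instant\tfast_avg\tslow_baseline\te_n"]
    for t, f in enumerate(np.asarray(f_series, dtype=float)):
        e_n = trk.update(f, dt)
        lines.append(f"{t}\t{t * dt}\t{f:.10g}\t{trk.fast_avg:.10g}"
                     f"\t{trk.slow_baseline:.10g}\t{e_n:.10g}")
    return "\n".join(lines) + "\n"
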