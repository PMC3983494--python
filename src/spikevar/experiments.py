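"""Reproducible experiment drivers: training protocols, model-variant
comparisons, and the maze novelty experiment.

The reference protocol organizes training data in 200 ms batches, 500
presentations per epoch (100 s of data per epoch), with the data
log-likelihood estimated by importance sampling at periodic checkpoints
(500 samples of 100 ms by default).  Desk-scale runs shrink the counts,
not the structure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_dynamics import (DualNetwork, SimulationState, SpikeRaster,
                            run_network, trace_from_raster)
from .free_energy import FreeEnergyTracker, windowed_free_energy
from .inference_eval import estimate_log_likelihood
from .learning_rules import (HebbianTraces, LearnerConfig,
                             fully_observed_gradient, naive_batch_update,
                             run_online_batch, variance_reduced_update)
from .synthetic_data import (Maze, MazeConfig, StairsConfig, make_mazes,
                             random_walk, stairs_raster, trajectory_to_raster)

__all__ = [
    "TrainingProtocol",
    "stairs_source",
    "train",
    "compare_variants",
    "epochs_to_threshold",
    "novelty_experiment",
]


@dataclass
class TrainingProtocol:
    """Training and evaluation schedule.

    Full-scale reference defaults: 200 ms batches, 500 presentations per epoch,
    importance-sampling evaluation (500 samples x 100 ms) every 500 epochs.
    """

    batch_ms: float = 200.0
    presentations_per_epoch: int = 500
    n_epochs: int = 10
    eval_every_epochs: int = 500
    eval_samples: int = 500
    eval_sample_ms: float = 100.0
    seed: Optional[int] = None
    carry_state: bool = False  # carry phi/eta across batches of one stream

    def __post_init__(self) -> None:
        for name in ("presentations_per_epoch", "n_epochs", "eval_every_epochs",
                     "eval_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def batch_bins(self, dt: float) -> int:
        return max(1, int(round(self.batch_ms / dt)))

    def eval_bins(self, dt: float) -> int:
        return max(1, int(round(self.eval_sample_ms / dt)))


def stairs_source(cfg: StairsConfig, batch_bins: int, dt: float = 1.0):
    """Batch source for the stairs task: each call yields a fresh batch
    with a random starting group (batches are excerpts of a long stream)."""
    def source(rng: np.random.Generator) -> np.ndarray:
        start = int(rng.integers(cfg.n_groups))
        return stairs_raster(cfg, batch_bins, dt=dt, seed=rng,
                             start_group=start).spikes
    return source


def train(net: DualNetwork, data_source: Callable, protocol: TrainingProtocol,
          variant: str = "vr_batch", cfg: Optional[LearnerConfig] = None,
          eval_data: Optional[np.ndarray] = None,
          on_divergence: str = "revert", max_step: float = 0.25):
    """Run the learn-mode training loop with the selected rule variant.

    ``data_source(rng)`` must return a visible clamp array of batch
    length.  The network is modified in place and returned together with a
    dict of logs: ``batch_log`` (per-batch free energy), ``eval_log``
    (importance-sampling checkpoints, when ``eval_data`` is given).

    If the weights diverge — NaN/Inf, a weight magnitude beyond 10 mV per
    unit EPSP, or an absurd free-energy magnitude, all far outside the
    physical regime (the naive rule is prone to
    this: its modulator is the full windowed free energy, so update
    magnitudes grow with everything the model mispredicts) — training
    stops, the most recent periodic checkpoint of sane weights is
    restored (the runaway regime can poison weights a batch or two before
    any after-the-fact check fires, so the restore point is kept a safe
    distance behind), and the log marks ``diverged=True`` with a final
    evaluation at the restored weights;
    with ``on_divergence='raise'`` a FloatingPointError is raised instead.

    Batch-mode updates are additionally screened before application: the
    exponential escape rate makes the score factor unbounded below, so a
    single oversized step (entry magnitude above ``max_step``) signals the
    runaway regime and is rejected rather than applied.
    """
    cfg = cfg or LearnerConfig(variant=variant)
    rng = np.random.default_rng(protocol.seed)
    dt = net.params.dt
    nb = protocol.batch_bins(dt)
    baseline = None
    traces = HebbianTraces.zeros(net, cfg.tau_g)
    tracker = FreeEnergyTracker(cfg.tau_g, cfg.tau_baseline)
    state = SimulationState.zeros(net.n_neurons) if protocol.carry_state else None

    batch_rows = []
    eval_rows = []
    diverged = False
    f_scale = None  # free-energy scale of the first batch, for early abort
    n_batches_seen = 0
    ckpt = (net.w_g.copy(), net.w_q.copy())  # last known-sane weights
    for epoch in range(protocol.n_epochs):
        for b in range(protocol.presentations_per_epoch):
            clamp = data_source(rng)
            if variant == "fully_observed":
                if net.n_hidden != 0:
                    raise ValueError("fully_observed requires a network with "
                                     "no hidden neurons")
                trace = trace_from_raster(net, SpikeRaster(clamp, dt=dt),
                                          state=state)
                f_hat = -windowed_free_energy(trace, variant="simplified",
                                              form=cfg.form)  # = log-lik
                net.w_g += cfg.mu_g * fully_observed_gradient(trace, form=cfg.form)
                e_stat = 0.0
            elif variant in ("naive_batch", "vr_batch"):
                trace = run_network(net, "learn", nb, clamp=clamp,
                                    rng_seed=rng, state=state)
                f_hat = windowed_free_energy(trace, form=cfg.form)
                if variant == "naive_batch":
                    dw_g, dw_q = naive_batch_update(trace, f_hat, cfg)
                    e_stat = f_hat
                else:
                    bl = f_hat if baseline is None else baseline
                    dw_g, dw_q = variance_reduced_update(trace, f_hat, bl, cfg)
                    e_stat = f_hat - bl
                    baseline = bl + cfg.baseline_decay * (f_hat - bl)
                if n_batches_seen < cfg.q_burn_in:
                    dw_q = np.zeros_like(dw_q)
                step = max(np.abs(dw_g).max(), np.abs(dw_q).max())
                if np.isfinite(step) and step <= max_step:
                    net.w_g += dw_g
                    net.w_q += dw_q
                else:
                    if on_divergence == "raise":
                        raise FloatingPointError(
                            f"runaway update (|dw|={step:.3g}) in epoch {epoch}")
                    batch_rows.append({"epoch": epoch, "batch": b,
                                       "f_hat": f_hat, "e_stat": e_stat})
                    net.w_g, net.w_q = ckpt
                    diverged = True
                    break
            elif variant in ("online", "simplified"):
                out = run_online_batch(net, clamp, traces, tracker, cfg, rng,
                                       state=state, variant=variant)
                f_hat = float(out["f_series"].sum())
                e_stat = float(np.abs(out["e_series"]).mean())
                if protocol.carry_state:
                    state = out["state"]
            else:
                raise ValueError(f"unknown variant {variant!r}")
            n_batches_seen += 1
            if protocol.carry_state and variant not in ("online", "simplified"):
                state = trace.final_state
            batch_rows.append({"epoch": epoch, "batch": b, "f_hat": f_hat,
                               "e_stat": e_stat})
            if f_scale is None and np.isfinite(f_hat):
                f_scale = abs(f_hat)
            sane = (np.isfinite(f_hat)
                    and abs(f_hat) < 5.0 * (f_scale or 1.0) + 1e3
                    and np.isfinite(net.w_g).all()
                    and np.isfinite(net.w_q).all()
                    and max(np.abs(net.w_g).max(), np.abs(net.w_q).max()) < 10.0)
            if sane and n_batches_seen % 25 == 0:
                ckpt = (net.w_g.copy(), net.w_q.copy())
            if not sane:
                if on_divergence == "raise":
                    raise FloatingPointError(
                        f"weights diverged to NaN/Inf in epoch {epoch}")
                net.w_g, net.w_q = ckpt
                diverged = True
                break
        if diverged:
            break
        if eval_data is not None and (epoch + 1) % protocol.eval_every_epochs == 0:
            est = estimate_log_likelihood(
                net, eval_data, n_samples=protocol.eval_samples,
                sample_duration_bins=protocol.eval_bins(dt), seed=rng)
            eval_rows.append({"epoch": epoch, "loglik": est.log_likelihood,
                              "se": est.standard_error,
                              "n_samples": est.n_samples})
    if diverged and eval_data is not None:
        est = estimate_log_likelihood(
            net, eval_data, n_samples=protocol.eval_samples,
            sample_duration_bins=protocol.eval_bins(dt), seed=rng)
        eval_rows.append({"epoch": epoch, "loglik": est.log_likelihood,
                          "se": est.standard_error,
                          "n_samples": est.n_samples})
    return net, {"batch_log": pd.DataFrame(batch_rows),
                 "eval_log": pd.DataFrame(eval_rows),
                 "diverged": diverged,
                 "config": {"variant": variant, **asdict(cfg)}}


def epochs_to_threshold(eval_log: pd.DataFrame, threshold: float) -> Optional[int]:
    """First checkpoint epoch whose log-likelihood reaches ``threshold``,
    or None if never reached."""
    hits = eval_log[eval_log["loglik"] >= threshold]
    return None if hits.empty else int(hits["epoch"].iloc[0])


def compare_variants(variants: Sequence[str], net_factory: Callable[[], DualNetwork],
                     data_source: Callable, protocol: TrainingProtocol,
                     eval_data: np.ndarray,
                     cfg: Optional[LearnerConfig] = None,
                     threshold_fraction: float = 0.5):
    """Train each variant from the same initial weights on identically
    seeded data streams, evaluating at every checkpoint.

    Returns ``(eval_table, summary)``.  ``eval_table`` has one row per
    (variant, checkpoint).  ``summary`` reports each variant's final
    log-likelihood and its epochs-to-threshold, where the threshold sits at
    ``threshold_fraction`` of the way from the worst initial checkpoint to
    the best final one (a scale-free speed criterion used to compare
    learning speeds between variants).
    """
    if len(variants) < 2:
        raise ValueError("need at least two variants to compare")
    tables = []
    logs = {}
    for variant in variants:
        net = net_factory()
        vcfg = LearnerConfig(**{**(asdict(cfg) if cfg else {}), "variant": variant}) \
            if cfg else LearnerConfig(variant=variant)
        _, log = train(net, data_source, protocol, variant=variant, cfg=vcfg,
                       eval_data=eval_data)
        t = log["eval_log"].copy()
        t["variant"] = variant
        t["diverged"] = log["diverged"]
        tables.append(t)
        logs[variant] = log
    eval_table = pd.concat(tables, ignore_index=True)
    lo = eval_table.groupby("variant")["loglik"].first().min()
    hi = eval_table.groupby("variant")["loglik"].last().max()
    threshold = lo + threshold_fraction * (hi - lo)
    summary = {}
    for variant in variants:
        t = eval_table[eval_table["variant"] == variant]
        summary[variant] = {
            "final_loglik": float(t["loglik"].iloc[-1]),
            "final_se": float(t["se"].iloc[-1]),
            "epochs_to_threshold": epochs_to_threshold(t, threshold),
            "diverged": bool(logs[variant]["diverged"]),
        }
    summary["threshold"] = float(threshold)
    return eval_table, summary


def _probe_free_energy(net: DualNetwork, maze: Maze, path, cfg: LearnerConfig,
                       rng) -> dict:
    """Mean free energy and novelty trace over one probe walk (no learning)."""
    raster = trajectory_to_raster(maze, path, seed=rng)
    traces = HebbianTraces.zeros(net, cfg.tau_g)
    tracker = FreeEnergyTracker(cfg.tau_g, cfg.tau_baseline)
    out = run_online_batch(net.copy(), raster.spikes, traces, tracker, cfg, rng,
                           learn=False, variant="online")
    return {"f_mean": float(out["f_series"].mean()),
            "f_series": out["f_series"], "e_series": out["e_series"]}


def novelty_experiment(maze_cfg: MazeConfig, n_hidden: int,
                       protocol: TrainingProtocol,
                       steps_per_batch: int = 100,
                       probe_every_epochs: int = 1,
                       probe_steps: int = 1000,
                       final_probe_steps: Optional[int] = None,
                       cfg: Optional[LearnerConfig] = None,
                       weight_sd: float = 0.002,
                       seed: Optional[int] = None):
    """Train on target-maze trajectories; probe both mazes as learning
    proceeds.

    At every probe, fixed-length walks are scored in the target and the
    test maze (mean free energy per step), and the novelty signal e_N(t)
    is recorded along a *shared* room trajectory rendered under both
    mazes' views, with per-bin labels marking replaced-room segments.

    A probe is also taken before any training (logged as epoch -1): at
    that point the two mazes are indistinguishable to the model.  The
    initial weights are deliberately small (``weight_sd=0.002``): larger
    random weights interact with the rasters' trace statistics through
    the convex escape rate and give the untrained network a spurious
    free-energy offset between the mazes, which would contaminate the
    novelty comparison.  The
    final shared-trajectory probe can be longer than the periodic ones
    (``final_probe_steps``); its first ``warmup_bins`` bins (five baseline
    time constants) should be discarded from statistics while the novelty
    tracker settles.

    Returns a dict with the trained network, the probe table, the final
    shared-trajectory novelty traces, and the replaced-room set.
    """
    rng = np.random.default_rng(seed)
    cfg = cfg or LearnerConfig(variant="online")
    target, test, replaced = make_mazes(maze_cfg, seed=rng)
    net = DualNetwork.random_init(maze_cfg.n_pixels, n_hidden,
                                  weight_sd=weight_sd,
                                  seed=int(rng.integers(2**31)))
    traces = HebbianTraces.zeros(net, cfg.tau_g)
    tracker = FreeEnergyTracker(cfg.tau_g, cfg.tau_baseline)

    probe_rows = []
    pre_path = random_walk(target, probe_steps, seed=rng)
    res_t = _probe_free_energy(net, target, pre_path, cfg, rng)
    res_x = _probe_free_energy(net, test, pre_path, cfg, rng)
    probe_rows.append({"epoch": -1, "f_target": res_t["f_mean"],
                       "f_test": res_x["f_mean"]})
    for epoch in range(protocol.n_epochs):
        for _ in range(protocol.presentations_per_epoch):
            path = random_walk(target, steps_per_batch, seed=rng)
            raster = trajectory_to_raster(target, path, seed=rng)
            run_online_batch(net, raster.spikes, traces, tracker, cfg, rng,
                             variant=cfg.variant if cfg.variant in
                             ("online", "simplified") else "online")
        if not np.isfinite(net.w_g).all():
            raise FloatingPointError(f"weights diverged in epoch {epoch}")
        if (epoch + 1) % probe_every_epochs == 0:
            probe_path = random_walk(target, probe_steps, seed=rng)
            res_t = _probe_free_energy(net, target, probe_path, cfg, rng)
            res_x = _probe_free_energy(net, test, probe_path, cfg, rng)
            probe_rows.append({"epoch": epoch,
                               "f_target": res_t["f_mean"],
                               "f_test": res_x["f_mean"]})

    # final shared trajectory, biased to visit replaced rooms
    shared = random_walk(target, final_probe_steps or probe_steps, seed=rng,
                         start_room=int(replaced[0]))
    res_t = _probe_free_energy(net, target, shared, cfg, rng)
    res_x = _probe_free_energy(net, test, shared, cfg, rng)
    in_replaced = np.isin(shared, replaced)
    return {
        "net": net,
        "probe_log": pd.DataFrame(probe_rows),
        "replaced_rooms": replaced,
        "shared_path": shared,
        "in_replaced": in_replaced,
        "e_target": res_t["e_series"],
        "e_test": res_x["e_series"],
        "f_target_series": res_t["f_series"],
        "f_test_series": res_x["f_series"],
        "warmup_bins": int(5 * cfg.tau_baseline / net.params.dt),
    }
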