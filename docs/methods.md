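# Methods

## Neuron and network model

Neurons are stochastic Spike Response Model (SRM) units with escape
noise.  The membrane potential of neuron *i* is

    u_i(t) = Σ_j w_ij φ_j(t) + η_i(t),

where φ_j is the presynaptic spike train filtered by an exponential
kernel with the membrane time constant τ, and η_i is a spike-triggered
adaptation potential (an exponential kernel of strength −η₀ and time
constant τ_adapt applied to the neuron's own spikes).  The conditional
intensity is the exponential escape rate ρ_i = ρ₀ exp[(u_i − ϑ)/Δu].
Self-connections are structurally absent: self-influence flows through
the adaptation potential only.

Time is discretized in bins of width dt.  The per-bin spike probability
is 1 − exp(−ρ dt), which enforces at most one spike per bin and stays a
probability at any rate.  Within a bin, potentials and intensities are
computed from traces reflecting spikes up to the previous bin, the bin's
spikes are sampled, and the traces are then updated — a spike can never
influence its own emission probability.  Traces propagate by the exact
per-bin solution of their differential equation (decay factor
exp(−dt/τ)), not forward Euler, so the recorded trace entering bin *t*
equals the analytic convolution Σ_f exp(−(t − t_f)/τ) over spikes
strictly before *t* to machine precision; a spike reaches the next bin's
potential with amplitude exp(−dt/τ).

Traces start at zero at each window unless a carried-over state is
passed explicitly (`SimulationState`); the carry-over path exists for
continuous trajectories such as the maze walks.

### Default parameters

| parameter | meaning | default |
|---|---|---|
| dt | time bin | 1 ms |
| τ | membrane/EPSP time constant | 10 ms |
| η₀ | adaptation strength | 0.1 mV |
| τ_adapt | adaptation time constant | 10 ms |
| ρ₀ | firing-rate scale | 1 kHz |
| ϑ | threshold | 0 mV |
| Δu | firing sensitivity | 1 mV |
| μ_G, μ_Q | learning rates | 1e−5 |
| τ_G | trace / fast-average time constant | 10 ms |
| τ_baseline | baseline time constant | 100 ms |
| batch | training window | 200 ms |
| initial weights | Gaussian, mean 0 | sd 0.01 |

A single `NeuronParams` applies to visible and hidden neurons alike
(nothing distinguishes their physiology, only their wiring).

## Two likelihood forms

Every likelihood-bearing quantity exists in two forms:

- **continuous_limit** — per-bin term X log ρ − ρ dt, the small-bin
  limit of the point-process likelihood.  All learning rules use this
  form; its weight-derivative gives the postsynaptic factor
  (X − ρ dt)/Δu.
- **discrete_exact** — per-bin term X log(1 − e^{−ρdt}) − (1 − X) ρ dt,
  the exact log-pmf of the Bernoulli sampler above.  This form is a
  proper probability mass function over binary rasters (it sums to one),
  and its score has exactly zero conditional mean under the sampler.

At the default rates ρ dt is of order one, so the two forms are *not*
numerically interchangeable.  The learning rules keep the continuous-
limit form; the enumeration oracle and every exactness test use the
discrete-exact form throughout, because only a mutually consistent
(sampler, likelihood, score) triple satisfies the normalization, score-
mean and unbiasedness identities to machine precision.  log ρ is always
computed as log ρ₀ + (u − ϑ)/Δu, never by exponentiating and taking the
log; the escape-rate exponent is clipped at ±500 purely as an overflow
guard.

## Free energy and learning rules

With visible spikes clamped to data and hidden spikes sampled from the
recognition network (whose weights w^Q have no rows onto visible
neurons), the instantaneous free energy per bin is

    F_t = − Σ_{i∈V∪H} [X_i log ρ^G_i − ρ^G_i dt]
          + Σ_{i∈H} [X_i log ρ^Q_i − ρ^Q_i dt],

its window sum F̂(T) the free-energy point estimate.  The rules:

- **fully_observed** — gradient ascent on the visible-only likelihood, a
  convex problem.
- **naive_batch** — generative weights follow the batch Hebbian gradient
  Σ_t pf_i(t) φ_j(t); recognition weights follow the score-function
  estimator −μ_Q F̂(T) Σ_t pf^Q_i(t) φ_j(t).
- **vr_batch** — identical, with F̂(T) replaced by the error signal
  e(T) = F̂(T) − F̄, where F̄ is an exponential moving average over
  previous batches (decay 0.1, effective window about ten batches).
  The baseline is independent of the current batch's hidden spikes, so
  the expected update is unchanged.
- **online** — Hebbian traces H_ij low-pass the per-bin outer products
  with time constant τ_G, and weights update every bin:
  Δw^G = +μ_G H^G dt, Δw^Q = −μ_Q e_N(t) H^Q dt.  Signs implement
  descent on F: positive covariance between H^Q and the free energy
  depresses the synapse.
- **simplified** — recognition weights tied to the generative weights;
  hidden neurons are driven by the forward dynamics as the posterior
  proposal.  Under the tie the hidden G- and Q-likelihood terms cancel,
  so the objective keeps visible terms only; synapses onto visible
  neurons keep the two-factor rule and synapses onto hidden neurons the
  three-factor rule, applied to the single weight set.

Updates scale with dt so the learning-rate semantics are per
millisecond.  Structural zeros (diagonals, visible recognition rows) are
preserved by every rule.

### The novelty signal

e_N(t) is the difference of two cascaded moving averages of F_t: a fast
one with time constant τ_G, and a slow baseline that filters the *fast*
average with time constant τ_baseline (so the baseline's effective time
scale depends on both constants).  Both averages warm-start at the first
observed value; a cold start at zero would fabricate a large novelty
transient at t = 0 that has nothing to do with the data and destabilizes
scaled-up online learning.  Consequently e_N is exactly zero under
constant input from the start, rises transiently in proportion to a step
change, and decays as the baseline catches up.

### Stability guards in the training driver

The exponential escape rate makes the postsynaptic factor unbounded
below (−ρ dt), so once a recognition potential wanders a few Δu above
threshold, the next batch's score explodes — a runaway that develops
within one or two batches.  The training driver therefore (a) rejects a
batch update whose largest entry exceeds 0.25 (an order of magnitude
above legitimate steps) instead of applying it, (b) keeps a periodic
checkpoint of known-sane weights and restores it when weights or the
free energy leave the physical regime, marking the run as diverged, and
(c) optionally delays recognition updates for a configurable burn-in
(`q_burn_in`) so the batch baseline can settle before the score-function
estimator starts drawing on it — during fast early learning the trailing
baseline lags the steeply decreasing free energy, and the error signal
would otherwise be dominated by that trend.  Weights themselves are
never clipped; divergence is surfaced, not hidden.

## Synthetic benchmarks

**Stairs.**  Three groups of ten visible neurons activate in a fixed
cyclic order; the active group fires Poisson at 700 Hz, inactive groups
at 1 Hz, and each activation lasts a Gaussian duration (mean 30 ms,
sd 10 ms, truncated at positive values, sampled by rejection).  The
pattern requires memory about three times the membrane time constant.
Per-bin spike probabilities use 1 − e^{−ρdt} (at 700 Hz and 1 ms bins
that is ≈ 0.50, far from the naive ρ dt = 0.7).

**Maze.**  Sixteen rooms (4×4 lattice; only lattice neighbors are
accessible) each carry a fixed gray-scale view image; pixel values map
affinely onto firing rates in [0.01, 9] Hz, and one visible neuron per
pixel fires Poisson while the agent is in the room.  Time is abstract:
one bin is a 100 ms step and the network constants are read in steps.
The agent's walk moves to a uniformly chosen neighbor at geometrically
distributed dwell times (mean 5 steps — change-points with multi-step
dwells, since the dwell distribution is a modeling choice here).  A test
maze replaces a configurable number of rooms (default 3 of 16) with
fresh views.

Views are procedurally generated digit-like glyphs (seeded random
strokes, blurred, mean gray level normalized), and all views — including
replacements — are histogram-matched to a single intensity palette.  The
mazes therefore differ only in the spatial *arrangement* of intensities:
distinguishing them requires having learned the views and their layout,
not their gray-level statistics.  Externally supplied image sets of the
right shape can be passed in instead of the procedural glyphs.

What the generators do not emulate: real handwritten digits, goal-
directed navigation, pixel correlations within a view beyond the stroke
structure, or any observation noise beyond Poisson spiking.  Passing
benchmarks here shows the learning machinery works under the stated
statistical conditions, not that it handles natural images or behavior.

## Evaluation

The visible log-likelihood is estimated by importance sampling: draw
hidden rasters from the recognition network clamped to the data, average
exp(−F̂) and take the log (stable log-sum-exp; delta-method standard
error).  The estimate is biased low at finite sample counts (Jensen) and
consistent as samples grow.  Data longer than the sample window (default
100 ms; the reference protocol uses 500 samples per window) is tiled
into non-overlapping windows whose estimates are summed — windows are
treated as independent, which is exact for the window-reset dynamics
used here.  With no hidden neurons the estimator returns the exact
complete-data log-likelihood.

On instances small enough to enumerate every hidden raster (guarded at
2^20), `oracle_marginal` computes the exact marginal, posterior,
expected free energy and KL gap with the discrete-exact form, and
`oracle_expectation` takes exact expectations of arbitrary per-raster
functionals under the recognition distribution.  These oracles are the
ground truth for the normalization, score-identity, unbiasedness and
bound tests.

## Scaled-down experiment protocols

The reference protocol (200 ms batches, 500 presentations per epoch,
evaluations of 500 × 100 ms samples every 500 epochs, rates 1e−5, up to
10^5 epochs) is impractically long for a test suite; the package's
experiments use the same structure at reduced sizes, chosen once:

- **Stairs comparison** — 30 visible + 12 hidden neurons, 2000 batches,
  μ_G = 5e−5 (compensating the much shorter run), μ_Q = 1e−7 with a
  50-batch burn-in (batch score-function steps larger than this enter
  the runaway regime described above; recognition learning contributes
  little to the likelihood at this scale, which is dominated by the
  generative weights of the hidden neurons), evaluation with 100 × 100
  ms samples on 500 ms of held-out data.  Under these conditions the
  hidden-neuron online model beats the visible-only model by ~250–300
  nats, the online and variance-reduced batch rules land within ~1% of
  each other, and the naive batch rule halts on runaway updates shortly
  after its recognition updates begin — the desk-scale face of its
  prohibitive gradient variance.
- **Variance scaling** — hidden counts {4, 8, 16, 32} with the visible
  count scaled to match, 500 independent 200 ms batches per size at
  fixed random weights, one recorded recognition synapse.  The weak-
  coupling prediction (update variance quadratic in network size for the
  naive rule, linear with baseline removal) presumes per-neuron
  free-energy terms whose variance does not itself grow with the
  network, so the fixed random weights scale as 0.04/√n_neurons, keeping
  the per-neuron synaptic input variance size-independent.  Measured
  slopes are ≈ 2 vs ≈ 1.3, and the variance ratio at N = 32 is of order
  10^4.
- **Maze novelty** — 2×2 rooms with 8×8 views, 2 rooms replaced (the
  4×4 default replaces 3 of 16; the tiny maze needs a larger replaced
  fraction for a short probe to resolve the gap), 64 visible + 10 hidden
  neurons, online rule with μ_G = 5e−4, μ_Q = 1e−6, 5000 batches of 100
  steps.  Initial weights use sd 0.002 here: at sd 0.01 the random
  weights interact with the rasters' trace statistics through the convex
  escape rate and hand the *untrained* network a reproducible
  free-energy offset between the mazes, which would contaminate the
  novelty comparison (the stairs experiments keep sd 0.01).  Probes run
  the same 20 000-step room trajectory through both mazes; the first
  five baseline time constants are discarded while the novelty tracker
  settles.  After training the altered maze carries a higher mean free
  energy (the excess concentrated in the replaced rooms, ≈ +1 nat per
  bin there), |e_N| is elevated inside replaced-room segments, and the
  pre-training probe shows no gap.

## Known limitations

- The batch score-function rules are only conditionally stable at
  scaled-up learning rates; the guards stop runaway runs rather than
  preventing them.  This mirrors the estimator's variance problem that
  baseline removal mitigates but does not remove.
- The continuous-limit learning objective is not exactly normalized at
  ρ dt ≈ 1, so learned weights optimize a slightly biased surrogate of
  the discrete sampler's likelihood; evaluation and learning share the
  same convention, so comparisons between variants are unaffected.
- The enumeration oracle is limited to a few neuron-bins (2^20
  configurations), so exactness is only ever verified on tiny instances.
- Importance sampling with the recognition proposal degrades when q is
  far from the posterior (early in training its effective sample size is
  small); reported standard errors make this visible.
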