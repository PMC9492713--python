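# Methods

This note documents the models and procedures implemented in `tdehmm`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not establish about real data.

## Model

### Time-delay embedding and reduction

Each subject's `channels × time` matrix is z-scored per channel (so
amplitude-dominant subjects cannot dominate the group covariance), embedded
with L lags symmetric around each sample (default L = 15, lags −7…+7; at
250–300 Hz this is a 50–60 ms window), and reduced with group-level PCA
fitted to the concatenated cohort.  The default keeps twice as many
components as channels.  Fewer components bias the model toward low
frequencies (they carry the most variance), which is why the reduction is
exposed in `EmbeddingConfig`.  Whitening is off by default: the state
covariances are meant to retain the relative variance structure of the
embedded space; `whiten=True` is available.

The embedding drops (L−1)/2 samples at each record edge rather than
zero-padding — padding would inject spurious covariance at the boundaries.
State time courses are re-aligned to original sample indices (offset
(L−1)/2, edge rows replicated) before any spectral or temporal
computation, so states and signals are never systematically lagged.

### Sign disambiguation

Source-reconstructed channels have arbitrary per-subject polarity, which
cancels cross-subject covariance structure if left unresolved.
`align_signs` builds an across-subject template of lagged cross-covariance
matrices (lags 0…7 by default, matching the embedding window) and
maximizes each subject's agreement with it by coordinate descent over
per-channel sign vectors, with pairwise flip moves to escape single-flip
local optima, iterating template refinement; ties break toward no flip, so
the procedure is deterministic.  An exhaustive per-subject search
(2^C sign vectors) is available for small channel counts and is used in
tests to verify that the greedy search attains the global per-subject
optimum.

Two ambiguities are inherent and harmless: a per-subject *global* sign
(flipping every channel of one subject leaves its covariances unchanged)
and a cohort-wide *per-channel convention* (flipping a channel in all
subjects leaves every agreement term unchanged).  Recovery is therefore
scored up to these two invariances.

### Variational Gaussian HMM

The observation model per state is a zero-mean multivariate Gaussian on
the reduced embedded space; only the covariance is modelled, since the
oscillatory content of interest lives in the (auto)covariance.  Priors are
weakly informative conjugates, chosen so the free-energy comparison across
restarts is meaningful; none is load-bearing at the default data sizes
(posterior counts are 10^4–10^5 per state):

* state precisions: Wishart with ν₀ = d+2 and scale chosen so the prior
  mean precision is the identity (data are PCA-scaled);
* transition rows: Dirichlet(1) plus a diagonal bonus of 10 pseudo-counts,
  encoding a mild expectation of persistent states;
* initial distribution: Dirichlet(1).

Inference alternates exact forward–backward smoothing (scaled domain,
scale floor 1e-300; log-space Viterbi with ties to the lower state index)
using expected log-parameters, with closed-form conjugate updates.  The
variational free energy −ELBO is computed every iteration from the
forward normalizers plus the parameter KL terms and is non-increasing; an
increase beyond tolerance raises an error (it indicates a broken update,
and in testing never occurs).  Convergence is declared at relative
free-energy change below `tolerance` (default 1e-5).  The stored posterior
is the one whose E-step produced the final free energy, so recomputing the
free energy from a converged fit reproduces the last trace entry.

Initialization: per restart, a seeded k-means on windowed log-power
features (25-sample windows) provides a smoothed one-hot gamma; this gives
reproducible diversity across restarts.  `best_of_runs` fits `n_runs`
restarts from seeds spawned deterministically from the global seed and
keeps the lowest-free-energy fit, retaining every restart's trace and
final value.  Mini-batch (stochastic) updates over subjects are available
(`batch_subjects`) for cohorts too large for full batch; they use
Robbins–Monro averaging of sufficient statistics, and the free-energy
monotonicity guarantee applies only to the full-batch default.

The forward/backward/Viterbi inner loops are numba-jitted when numba is
importable, with a pure-numpy fallback; a property test asserts the two
paths agree to 1e-12.

### State spectra and frequency modes

Per subject and state, power spectral densities, cross-spectra and
magnitude-squared coherence over 1–45 Hz are estimated with DPSS
multitapers: 2 s windows, 50% overlap, time-half-bandwidth 4, 7 tapers
(~0.5 Hz resolution at typical sampling rates; all config-exposed).
Within each window the data are weighted *sample-wise* by the state's
posterior probability, with a matched power normalization (exact for white
signals; a Parseval test bounds the bias at 15% for band-limited
signals).  Pointwise weighting is essential at the study conditions: mean
dwell times (~50–200 ms) are much shorter than the 2 s window, so
weighting whole windows by their mean gamma would mix all states'
spectra; the window-mean variant is still available
(`weighting="window-mean"`) for long-dwell regimes.  States never active
for a subject (max gamma below 0.1) are flagged missing (NaN), never
imputed, and excluded pairwise from group averages.

Stacked spectra (subjects × states × channels, rows over frequency) are
factorized with NNMF (Frobenius loss, 20 seeded random restarts).  The
restart whose modes have the fewest total local maxima — counted after a
3-bin moving average, ignoring bumps below 5% of the mode's peak — is
kept; this operationalizes "choose the most clearly unimodal solution"
reproducibly.  Modes are sorted by peak frequency, normalized to sum 1
(so band projection is a weighted mean and coherence stays in [0,1]),
and labelled by the anchor band containing their peak: delta/theta
2–8 Hz, alpha 8–14 Hz, beta 14–30 Hz, low gamma 30–45 Hz.  The low-gamma
mode is carried through the data structures but flagged out of group
statistics by default (low SNR at high frequencies); the same mode
profiles are applied to power and coherence.

### Temporal metrics

Five per-subject summaries: fractional occupancy (column means of gamma),
lifetimes, interval times, switching rate (changes/second), and
off-diagonal transition probabilities (diagonal zeroed, rows renormalized;
rows of never-left states are NaN).  Lifetimes and intervals need a hard
path; the Viterbi path is used because it respects the Markov prior and
avoids single-sample flicker (per-sample argmax is available).  Runs
touching the record edges are *included* by default, which keeps the
bookkeeping exactly closable (per state: occupancy + intervals + time
outside first/last visit = record length, asserted on random paths);
`censor_edges=True` drops them from lifetime distributions, since their
true duration is unknown.  Both pooled and per-subject-averaged
lifetime/interval distributions are provided.  Absolute values of these
metrics depend on the prior hyperparameters and the state-exclusivity
assumption; only relative comparisons (between states or groups) are
meaningful, which is what the statistics layer tests.

### Statistics

* **State vs rest**: observed statistic per state is the mean over
  subjects of (state value − mean of other states); the null permutes
  state labels within subject.  Correction over the family is
  max-statistic by default (BH optional).
* **Two-group**: two-sided permutation test on the Welch t statistic
  (mean-difference optional), p = (1 + #{|null| ≥ |obs|})/(N+1); exact
  enumeration of all splits for small groups.  Cohen's d uses the pooled
  n−1 SD; its 95% CI is bootstrap BCa (scipy), falling back to the
  percentile interval when BCa degenerates on very small samples.
* **BH-FDR** over the states × bands family at q = 0.05 (statsmodels).
* **NBS**: edge-wise two-sample t statistics thresholded at the two-sided
  critical t for `edge_alpha` (default 0.01) uncorrected; connected
  components of supra-threshold edges (scipy csgraph) are scored by edge
  count against the permutation null of the maximal component size,
  giving FWER-corrected component p-values.  Node-level measures enter as
  self-edges.  The edge-forming threshold governs sensitivity: diffuse
  weak effects want lenient thresholds, focal intense effects strict
  ones — with 630 edges at the default threshold the null's largest
  chance component is typically ≥3 edges, so a small intense subnetwork
  should be tested with a stricter `edge_alpha` (the planted-subnetwork
  tests use 1e-3).

All permutation machinery is seeded and reproducible, and every p-value
respects the 1/(N+1) lower bound.

## Synthetic data

The generator emulates the features the model exploits: first-order
Markov switching; per-state oscillators with channel loadings; within-
state phase-coupled channel pairs (a coupled channel mixes a phase-lagged
copy of its partner's oscillation with weight `strength`); white Gaussian
sensor noise (no 1/f background — this keeps analytic spectral oracles
exact); lognormal per-subject amplitude variability; per-channel sign
corruption; and group effects that are multiplicative on state power
(amplitude × √multiplier), additive on coupling strength, and monotone on
occupancy (raising a state's self-transition).  Oscillator phases reset
randomly at every state entry, so states are not phase-continuous and the
spectral contrast is exactly the covariance contrast the HMM assumes.
One global seed spawns per-subject substreams, so individual subjects are
stable under cohort resizing.

The reference cohort (`default_cohort_spec`) has K = 4 states at
5/10/20/35 Hz — one per canonical band — over 12 channels at 250 Hz,
120 s per subject, 6 subjects, self-transition 0.98 (mean dwell 200 ms),
oscillator amplitude 1, noise SD 0.2, subject amplitude SD 0.15.  Every
channel oscillates at its home frequency at all times, with amplitude 1
when its home state is active and 0.3 otherwise: states modulate ongoing
rhythms rather than switching them on and off, as cortical networks do.
This matters: with on/off states, embedding windows that straddle a state
transition lie far from every state's covariance, and the
minimum-free-energy solution dedicates a state to those windows instead
of recovering the planted states.  Under the modulation design the fitted
model recovers the planted states with ~0.97 mean posterior on the true
state, occupancy errors ~0.01 and transition-probability errors ~0.003.

What passing these tests shows: the inference, spectral estimation,
metrics and statistics are mutually consistent and recover known
structure at realistic SNR.  What they do not show: robustness to 1/f
backgrounds, non-sinusoidal or non-stationary rhythms, volume-conduction
leakage, artifacts, or heterogeneous head geometry — real-data features
the generator deliberately omits.

### Effect-size calibration and detection power

The planted two-group experiments use n = 20+20 subjects and calibrate
the alpha-power multiplier to a subject-level Cohen's d ≈ 0.7
(multiplier exp(0.7 × 0.3), since the subject amplitude SD of 0.15 puts
the log band-power SD near 0.3) — the magnitude typical of reported
patient-vs-control band-power differences.  At this effect size the
BH-corrected family test (one true effect among 9 state × band members)
has analytic power of only ~0.2–0.3: BH with one true effect needs
p ≲ 0.05/9, i.e. |t| > 2.95 at df 38, while the noncentrality is
0.7·√10 ≈ 2.2.  The measured detection rate (~0.1–0.2) agrees; a single
significant detection at this n is possible but not typical — an honest
property of the statistics at this effect size and sample size, reported
as such by the acceptance script rather than tuned away.

## Problem sizes and numerical choices

Tests and the acceptance script run the reference cohort at 6 subjects ×
120 s (≈180k embedded samples, 24 PCs) with 3 restarts and up to 60
iterations at tolerance 1e-6 — chosen as the smallest configuration at
which every recovery quantity is stable across seeds.  Exact-inference
oracles enumerate all K^T paths for K ≤ 3, T ≤ 8 and agree to 1e-10.
Calibration experiments use 100–200 null replicates at 300–500
permutations.  Degenerate inputs are handled explicitly: constant data
give p = 1; zero pooled SD raises; empty state paths raise; non-PD
covariance updates are symmetrized and jittered with a warning; NaN
emissions name the offending time point.

## Known limitations

* Gaussian observation model: heavy-tailed artifacts will fragment states.
* No leakage/orthogonalization correction and no 1/f background modelling.
* The NNMF mode decomposition is non-convex; the unimodality-selected
  restart is reproducible given the seed but not guaranteed globally
  optimal.
* Stochastic (mini-batch) inference trades the monotone free-energy
  guarantee for memory/compute; use full batch when feasible.
* Temporal metrics are model-relative quantities, not biological
  constants; compare them only across states or groups inferred under the
  same configuration.
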