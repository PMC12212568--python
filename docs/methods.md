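# Methods

## Model

Observations are spike-count vectors k(t) = {k_1(t), ..., k_N(t)} over N
neurons in bins of width Δt (default 50 ms). Conditional on hidden state
i, neuron n fires Poisson with mean λ_ni Δt and neurons are independent,
so the emission probability is the product of per-neuron Poisson pmfs.
The hidden state follows a first-order Markov chain with row-stochastic
transition matrix Γ; initial distributions π are treated as auxiliary
per-trial variables — a model is characterised by (Γ, Λ) alone. Reported
log-likelihoods always include the log k! constants, so values are
comparable across models and directly usable in BIC/AIC.

The categorical (Multinoulli) benchmark replaces the count vector by one
of N+1 symbols per bin (which single neuron fired, or silence) at much
shorter bins (default 5 ms); its emissions convert back to rates via
λ = −log(1 − e)/Δt. The collision probability
1 − (1−p)^N − N p (1−p)^(N−1) with p = 1 − exp(−λΔt) quantifies when the
single-spike assumption fails; it reaches 0.26 for 100 neurons at
5 spikes/s in 2 ms bins, which is why the categorical code is restricted
to small ensembles and bins of at most ~10 ms.

## Training

All Poisson-family models share one EM engine:

- **E-step**: forward–backward with per-bin normalisation of the forward
  variables and accumulated log scale factors, batched across trials (all
  trials share a bin count, so the recursion runs on (trials × states)
  arrays). Correctness is pinned to a brute-force path-enumeration oracle
  in the tests (m ≤ 3, T ≤ 6, agreement to 1e-10) and cross-checked
  against an independent HMM library's likelihood.
- **M-step**: π per trial from q_i(1); Γ and Λ from numerators and
  denominators pooled over trials. Rates are clamped to a floor of
  0.001 spikes/s after every update so emissions stay proper. A state
  with vanishing expected occupancy triggers a warning; its transition
  row is set uniform and its rates to the floor.
- **Convergence**: relative objective change < 1e-6 AND largest parameter
  change < 1e-6, where the parameter change is measured on Γ entries and
  on expected counts λΔt (dimensionless scale). Maximum 1000 iterations.
  The categorical model additionally requires the emission-matrix change
  below 1e-6.

**Sticky training** monitors diag(Γ) across the M-step: a reset fires when
some self-transition has converged (|γ′_ii − γ_ii| < ε, ε = 5·10⁻⁵) to a
value below θ. The reset restores a single rolling snapshot (Γ*, Λ*) — the
most recent iterate with all γ_ii ≥ θ, the initial guess qualifying at
iteration 0 — and applies a uniform random permutation to the columns of
Λ* (preserving the multiset of rate vectors; π untouched). The iteration
budget is shared across resets. Because the parameter tolerance (1e-6) is
stricter than ε, EM cannot converge while a diagonal sits below θ without
first triggering a reset, so `converged=True` structurally implies
min γ_ii ≥ θ; a final defensive check enforces this. The convergence
tolerance applied before a reset is identified with ε.

**Dirichlet-MAP training** adds a_ij − 1 pseudo-counts to the transition
update and monitors the log-posterior LP = LL + Σ (a_ij − 1) log γ_ij.
The Dirichlet normalising constants are omitted everywhere (LP, modified
BIC/AIC, held-out LPv): they do not depend on the parameters and cancel in
all comparisons at fixed prior. Hyperparameters come from pinning the
prior mode: a_ii = 1 + γ̄(m−1)(ā−1)/(1−γ̄) with defaults γ̄ = 0.9,
ā = 1.1; a_ii is never rounded.

**Initial guesses**: Γ_init = θI + (1−θ)U with U a row-normalised
symmetric uniform matrix (θ = 0.8 Poisson, 0.9 categorical), so sticky
training always starts with a valid snapshot; rates uniform between the
smallest and largest per-neuron mean rates in the training data; π
uniform (Poisson) or concentrated on state 1 (categorical), whose emission
rows start with almost all mass on the *silence* symbol — placed at
position N+1 in this package's symbol layout, the only physically sensible
assignment.

## Selection, decoding, comparison

Cross-validation splits trials into 5 folds (seeded shuffle, contiguous
blocks), trains on the complement from many random guesses, and pools the
held-out log-likelihood across folds and guesses; held-out trials use the
stationary distribution of the fitted Γ as their initial distribution.
The slope elbow rule is formalised as the largest discrete
second-difference decrease of the mean curve. BIC/AIC use the full
dataset, K = m(m−1) + mN (π excluded) and D = total bins across trials;
non-converged fits are excluded from score averages but counted, since
systematic non-convergence (e.g. on swap-shuffled data) is diagnostic.
The SD of pooled CV scores is computed jointly over folds and guesses and
labelled as such.

Posterior decoding assigns each bin its maximum-posterior state, with ties
broken towards the lowest index and bins below a 0.8 confidence threshold
marked undecided (-1); the comparison index decodes with no threshold.
The default decoding initial distribution solves πᵀ(I − Γ + U) = 1ᵀ; the
fixed-first-state alternative is available with a configurable burn-in
window (default 0.4 s) whose bins are marked undecided. Viterbi decoding
is standard log-space dynamic programming.

D(Θ) is the total squared difference between observed counts and the
decoded state's expected counts on a validation set; ρ = D(Θ₁)/D(Θ₂).
States are matched by minimum-cost assignment on Euclidean distances
between rate columns (scipy's Hungarian solver, test-pinned to exhaustive
permutation search). The shuffled null permutes Λ's state columns and each
Γ row's off-diagonal entries within the row (diagonals and row sums
preserved; neuron identity preserved). On ground-truth Poisson surrogates
this null is narrowly concentrated around 1: decoding is dominated by the
emissions, which identity shuffles preserve, so the null's discriminative
power is limited to regimes with strongly overlapping states (such as
small real-data ensembles); the tests assert the concentration property
rather than a tail probability.

## Simulators

The MMPP reads Γ (referenced to a 50 ms bin) as a continuous-time
generator: exit rate (1 − γ_ii)/Δt_ref from state i, jump law
γ_ij/(1 − γ_ii), dwell times exponential with mean Δt_ref/(1 − γ_ii)
(KS-tested). Spike trains restart their exponential inter-spike clock at
each state switch — exact under memorylessness, not an approximation.
Initial states are drawn from the stationary distribution of Γ. The random
variant draws diagonals U(0.8, 1), off-diagonal row mass by normalised
uniform draws, and rates U(0, 30) spikes/s over 10–20 neurons, 50 trials
of 14 s — the reference surrogate-session conditions; a fitted-parameter
variant simply runs the generator on a trained model's (Γ, Λ). What the
MMPP does *not* emulate: refractoriness, within-state rate drift,
non-Poisson count dispersion, and neuron–neuron correlations beyond the
shared state — passing recovery tests therefore validates the algorithms
under their own assumptions, not the Poisson assumption itself on real
data.

The clustered LIF network (4000 E / 1000 I neurons; 10 clusters of 360
potentiated by J₊ = 2.2 with depression J₋ = max(1 − γ(J₊−1)f/Q, 0)
between clusters; exponential synaptic currents; forward Euler) produces
metastable cluster switching. Desk-scale runs use the full-size topology
with a 0.05 ms Euler step for ~10 s, which preserves the switching
dynamics; the 0.005 ms step of the reference parameterisation is used in
the single-neuron accuracy test (closed-form LIF period matched within
1%). A `scale` knob shrinks the population with 1/scale weight
compensation for quick smoke tests; strongly scaled-down networks fire at
realistic rates but lose metastability, so the switching check always uses
the full-size topology.

Controls: the circular shuffle rotates each spike train independently
within its trial (per-trial wrap; preserves each train's count exactly);
the swap shuffle permutes the time bins of each trial jointly across
neurons (within-trial; preserves the multiset of population count
vectors). Both conservation laws are asserted exactly.

## Problem sizes and numerical choices

The test suite validates the sticky guarantee over 50 randomised fits
(half generated with fast-switching adversarial diagonals), rate recovery
and ρ at the full reference session size (20 neurons, 50 trials × 14 s),
and BIC selection on three sessions with true m ∈ {2, 3, 4}, 10 trials of
7 s, 25 guesses per candidate m — sizes chosen so the whole suite runs in
minutes on one CPU while keeping every check at or above the statistical
resolution its tolerance requires. Scores and seeds flow through
`numpy.random.default_rng` throughout; every simulation, initial guess and
shuffle is reproducible from its seed.

Known limitations: trials must share a bin count (unequal durations are
truncated to the shortest trial); the semi-Markov and GLM-modulated
extensions of the transition model are out of scope; the categorical model
refuses no inputs but warns above 10 ms bins, where its single-spike
assumption fails.
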