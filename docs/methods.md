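# Methods

## Model

The agent is a fully connected recurrent network of N tanh units whose
recurrent weights have a fixed ("structural") component and an episode-local
plastic component:

    x(t) = W_in i(t) + (W_rec + A ⊙ P(t)) r(t−1)
    r(t) = tanh x(t)
    o(t) = softmax(W_out r(t))          — policy over the two responses
    m(t) = w_mod · r(t)                 — scalar neuromodulatory output
    v(t) = w_val · r(t)                 — critic value estimate

Plasticity is neuromodulated Hebbian learning with an eligibility trace:

    P(t+1) = P(t) + m(t) H(t)           (pre-update trace)
    H(t+1) = η x(t) r(t−1)ᵀ + (1−η) H(t)

P is zeroed at episode start only; x, r and H are additionally zeroed at
every trial start, so plastic weights are the sole memory across trials.
With η → 1 the rule telescopes to P(t+1) = P(t) + m(t) x(t−1) r(t−2)ᵀ,
which the test suite checks exactly against a stepwise oracle.

m(t) is a raw linear readout (no squashing). η is trained through a sigmoid
reparameterization so it stays in [0, 1]. The critic readout w_val is an
additional linear head used only by the training loss, never by the
forward policy.

## Task

Each episode draws 4–9 items as random binary vectors of length 15 and a
random latent order. A trial has exactly four steps: both stimuli are
presented (concatenated, slots 1 and 2) at step 1; the response is sampled
from the policy at step 2 (outputs at all other steps are ignored); the
signed reward (±1) and a one-hot copy of the response are fed back at
step 3; step 4 is a delay. The standard episode is 20 adjacent-pair trials
followed by 10 trials over all ordered non-identical pairs; episode
performance is the fraction correct over the last 10. The list-linking
protocol trains two 4-item sub-lists (10 adjacent trials each), then either
4 trials on the junction pair or — in the sham control — a single trial on
a non-linking pair, followed by one test trial from the full 8-item list.
Adjacent-phase pairs are sampled i.i.d. uniform with replacement and the
slot order of every pair is randomized; conditional analyses ("pair first
shown at trial 20", "no prior CD exposure") exploit that i.i.d. structure
to sample the conditional schedule distribution directly rather than by
rejection.

## Outer loop

Structural parameters (W_in, W_rec, A, W_out, w_mod, w_val, η) are trained
across episodes by advantage actor-critic. Rewards of the last 10 trials
are multiplied by 4 in the loss (the reward input to the network is never
rescaled); returns are discounted (γ = 0.9 default) over the flattened
120-step sequence; the advantage at each response step is return minus the
critic value, treated as a constant in the policy-gradient term and
standardized across the batch. An entropy bonus (0.03) and a value-error
term (coefficient 0.05) complete the loss. Gradients are taken through
every time step *including the plastic updates* by a hand-written
reverse-mode pass over the rollout tape; because H and r are zeroed at
trial starts, the within-trial trace states are reconstructed from the
stored trial-start P, so memory scales with trials (not steps) times N².
A finite-difference check (N=5, two-trial episodes, every parameter,
relative error < 1e-4) guards this machinery. Optimization is Adam
(lr 1e-3), global gradient-norm clipping at 1.0, batches of 16 episodes
per update, float32 rollouts. Episodes that diverge numerically (the
plastic loop x → H → P → x has no intrinsic bound) abort that batch; the
update is skipped, and training halts with the last good parameters only
if divergence recurs.

Two outer-loop choices matter and were set by explicit experiments:

* **Discount γ = 0.9, not 1.** The cross-trial "learning-to-learn" credit —
  how an early-trial plastic change improves late-trial choices — flows
  through the *differentiable* plasticity path, which does not involve the
  return at all. The score-function term only needs to credit a response
  with its own (next-step) reward. Undiscounted returns therefore add
  variance (the advantage inherits the noise of all future trials) without
  adding usable signal, and measurably stall learning.
* **Advantage standardization** per batch, a conventional variance-reduction
  device; without it the policy and value terms dominate the clipped
  gradient norm and the small plasticity-pathway gradients are drowned.

## Initialization

Initialization is the one place this implementation departs from plain
zero-mean i.i.d. scaling, because two bootstrapping obstructions were
identified experimentally (by constructing working networks by hand and by
measuring inter-batch gradient correlations, which are ≈ 0 at a naive
initialization):

1. **Recurrent echo.** The eligibility trace available when feedback
   arrives pairs post-synaptic activity with r(2), the recurrent image of
   the stimulus representation. With a purely random W_rec, r(2) is an
   incoherent rotation of r(1), so early Hebbian associations cannot
   transfer to later presentations of the same stimulus. W_rec is
   initialized as 0.4·I plus zero-mean noise (gain 0.3/√N); the identity
   component is an ordinary trainable parameter afterwards.
2. **Coherent plasticity coefficients.** A Hebbian event shifts population
   activity by (A ⊙ (w vᵀ)) v = w ⊙ (A v²); with zero-mean A this is a
   random per-neuron resigning of the stored pattern. A is initialized with
   a small positive mean (0.004) and like-sized noise. The scale is O(1/N),
   not O(1/√N): stored patterns have squared norm ≈ N/2, so coefficients of
   order 1/N keep single-trial plastic effects comparable to — not
   dominating — the base dynamics. With O(1) coefficients the network
   saturates and nothing trains.

The policy readout starts at gain 1.0/√N and the modulator readout at
0.5/√N; η starts at 0.5.

## Scaled study conditions

The reference configuration (N = 200, lists 4–9, 30 000 episodes) is
supported via config but desk-scale analyses use N = 100 and lists of 4–6
items: criterion-level learning checks train for 8 000 episodes (~2 min on
one CPU), while geometry and mechanism analyses use the same configuration
trained for 48 000 episodes (~9 min), since representational geometry
(readout anti-alignment, input-block subtraction coding) matures more
slowly than raw accuracy. Under these conditions trained runs reach
~0.95–0.98 last-10 accuracy and consistently land in the reinstatement-
based ("cognitive") solution class on the seeds tested; the
reward-modulated ("passive") class is expected to appear under other seeds
or settings, as in the reference experiments.

Two quantities are known not to reach their full-scale values at this
scale and are reported as measured: the slot-block correlation of W_in
strengthens steadily with training (≈ −0.17 at 8 000 episodes, ≈ −0.5 at
48 000) but has not saturated at the desk-scale budget, and the trained η
stays near its initialization (~0.55) — at these settings the loss is
nearly flat in η, so the trace-decay rate is not pushed toward 1.

## Probes and derived quantities

* **Decision axis**: difference of the two W_out rows (the rows are
  strongly anti-correlated in trained networks, so either row carries the
  same information).
* **Single-item probes**: with plastic weights frozen, one item is
  presented alone in slot 1 for two steps from a trial-reset state;
  ψ_t1 = r(1), ψ_t2 = r(2). "Alignment" is the Pearson correlation of
  ψ_t2 with the decision axis (cosine similarity is available as an
  option). All probes are read-only.
* **Stepwise tracking**: rollouts can snapshot P at entry to a chosen trial
  and after each of its four steps; alignment curves recomputed per
  snapshot give per-step deltas. Deltas at steps 1–2 are identically zero
  (the trace is empty there) — asserted, not assumed.
* **Recoded basis**: for unit vectors v (item) and w (shared axis), the
  first-order change of item X's alignment under a Hebbian perturbation of
  the plastic weights is the bilinear form
  S_X(v, w) = c_Xᵀ D_X [w ⊙ (A (v ⊙ ψ_t1(X)))], with D_X the tanh Jacobian
  and c_X the Pearson-alignment gradient at the probe operating point
  (a zero-linearization option supports the closed-form uniform-plasticity
  check). The fit alternates two exact maximizations of Σ_X S_X² — v_X
  closed-form given w; w as the top eigenvector of a small Gram matrix
  given the v's — so the objective is monotone; seeded restarts (20 by
  default) guard against local optima, and per-item signs are fixed so
  every induced shift is positive. The modulator's sign at apply time is
  deliberately not folded into the basis. Note that at desk scale the
  trained A retains much of its positive-mean initialization, so the
  recoded vectors correlate with the raw ψ_t1 far more strongly (~0.6)
  than heterogeneous full-scale plasticity would allow; reinstatement
  conclusions here rest on the delta analyses and the
  reinstatement-vs-shift association, not on recoded-vs-raw dissimilarity.
* **Noise band** for "no reinstatement" statements: the central 95%
  interval of correlations against 1 000 random unit vectors.
* **Solution classifier**: failed if mean last-10 accuracy ≤ 0.55; else
  passive if the modulator's reward split (|mean m | correct − mean m |
  error|) is larger at step 3 than at step 4, else cognitive. Thresholds
  are config constants; list-linking accuracy on distant cross-list pairs
  is reported alongside as a cross-check.

## Synthetic fixtures

The planted-network fixture constructs StructuralParams plus a P whose
single-item probe alignments equal a requested target sequence *by
construction*: exactly antisymmetric readout rows, slot-2 input block equal
to the negated slot-1 block, and P solved by least squares to place each
ψ_t2 at the target correlation, with all activations at scale 3e-4 so the
tanh is identity to O(1e-7). It exercises every probe and reinstatement
analysis with zero training and exact expected values. What fixtures do
not emulate: trained networks' saturating activations, heterogeneous
plasticity, and noise correlations — conclusions about those rest on the
trained-network tests.

## Numerical and degenerate-input choices

Pearson correlations return NaN for zero-variance inputs rather than
raising. The decision axis of an all-zero readout is flagged degenerate.
Non-finite activations abort an episode with the step index (plastic
weights can grow without bound; failures are loud). Checkpoints are HDF5
with a JSON manifest and SHA-256 content hash; loading verifies the hash.
PCA centers but does not scale features. Significance statements use
two-sided tests at α = 0.05 with runs as the sampling unit; permutation
nulls are seeded.

## Known limitations

* Desk-scale training does not reproduce the full-scale values of the
  input-block anti-correlation (−0.9) or the trained η ≈ 1; see above.
* The "no transfer without prior pairing" control is approximate at desk
  scale: removing CD exposure shrinks C's step-4 alignment shift about
  five-fold but not to statistical zero, because 15-dimensional binary
  stimuli overlap substantially and N=100 leaves little room to
  decorrelate their representations — D's reinstatement bleeds into C's
  probe. The coupled-vs-uncoupled *contrast* is large and reliable.
* The recoded-basis objective is one defensible operationalization of
  "patterns that produce appropriate learning under heterogeneous
  plasticity"; other recoding objectives (e.g. with interference
  penalties) could identify different vectors.
* The sham-control "distant pair" advantage is qualitative and depends on
  where the near/far boundary is drawn; the package reports the full
  per-pair table.
* No weight decay of P within episodes, no Dale's law or sparsity, and at
  most two response options, by design.
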