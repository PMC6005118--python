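# Methods

## Generative model

The task world is an 8×8 array whose cells are empty, target, or canceled
target. The agent's generative model is a discrete POMDP with hidden states =
fixation locations, 64 saccadic actions with deterministic transitions
(`B(u)` columns are unit vectors at the destination — saccades always land
where intended and do not depend on the current location), a delta initial
prior `D` at the start location, and two outcome streams per fixation:

* **visual**: white / black / red, likelihood held as Dirichlet counts
  `a` (column-normalized to `A1`), the only uncertain mapping in the model;
* **proprioceptive**: the identity likelihood `A2`, making the fixated
  location fully observable.

Each fixation epoch delivers two visual samples: the *onset* appearance and
the *offset* appearance after the cancellation rule fires (black→red). Both
update the Dirichlet counts; policy re-evaluation happens after the offset
observation, so a just-canceled target is already devalued when the next
saccade is chosen.

The multiscale variant factorizes location into quadrant × subquadrant × cell
(quadtree order upper-left, upper-right, lower-left, lower-right, applied
recursively; left-hand values are 0 and 2 at every level). Outcomes are the
target density of the fixated quadrant (0–16) and subquadrant (0–4) and the
fine white/black/red channel, plus one 4-way identity proprioceptive channel
per factor. The density channels count targets whether or not they are
canceled — coarse vision is color-blind; only the fine channel registers
cancellation. Density outcomes are exact integer counts rather than quantized
shades: the simplest faithful reading of "target density".

## Belief updating

State inference sweeps over hidden-state factors: per-time expected
log-likelihood messages (averaged over the other factors' beliefs) combine
with forward/backward transition messages and are renormalized, iterated to a
fixed point (cap 16 sweeps, convergence at 1e-8 max change, 1e-16 log
stabilization). For a single factor one sweep reaches the exact smoothed
posterior, which the tests verify against brute-force enumeration over state
sequences (≤1e-6, observed ~1e-15). The free-energy diagnostic uses the
mean-field expression over time points and factors; it upper-bounds surprise
−ln P(o) for any normalized beliefs and is tight whenever the exact posterior
factorizes (single-epoch models, or deterministic transitions as in the task
models) — the bound and tightness tests are designed around exactly those
cases.

## Policy evaluation

Expected free energy per policy, summed over its horizon:

* **expected cost** −E[ln P(o)] with ln P(o) = log-softmax(C) per modality.
  Defaults C_visual = (0, +4, −4) for (white, black, red); proprioceptive
  preferences are uniform in the healthy model.
* **salience** (state information gain): computed exactly by enumerating
  joint outcomes over the joint state space, with a fast path returning zero
  when the predictive state is already certain. In the cancellation models
  the identity proprioception makes this term identical (zero) for every
  policy — the structural reason cost and novelty alone drive search.
* **novelty** (likelihood information gain): for a one-observation update the
  Dirichlet KL has the closed form
  `ln a0 − ln a_i + ψ(a_i + 1) − ψ(a0 + 1)`, averaged over predicted
  outcomes and states. Verified against 2-D quadrature of the KL integral on
  the simplex. Novelty is evaluated per predicted state column (exact for
  the delta predictions that deterministic saccades produce).

Policies default to depth 1 (64 single-saccade policies re-evaluated every
epoch; depth is configurable, at combinatorial cost). The policy posterior is
softmax(ln E − γ·G) with fixed precision γ = 1; the precision-update
(dopaminergic) dynamics of the full scheme are deliberately out of scope.
A past-free-energy term would be policy-constant at depth 1 and is omitted.

## Parameters and defaults

| parameter | default | meaning |
|-----------|---------|---------|
| e0 | 0.25 | baseline Dirichlet count per outcome per column |
| e1 | 0.0625 | extra count on the true outcome ("weak but accurate" target knowledge; P(black at a target) ≈ 0.38 vs 0.31 baseline) |
| c_black / c_red | +4 / −4 | visual log-preferences (white = 0) |
| γ | 1 | policy precision |
| η | 1 | learning rate (count mass added per observation) |
| κ (A1) | 100 | count inflation of neglected-side columns |
| b (E), C2 | 4 | log-units of policy-prior / proprioceptive-preference bias |
| start | (3, 3) | trial start location |
| trial length | 20 saccades (40 for model comparison) |

e1 is kept well below e0 so that initial target beliefs are genuinely weak:
one observation then dominates the column (one-shot learning), and prior
preference cannot pull a lesioned agent back across the midline — novelty
differences are bounded by ln 3 nats, so strong initial target beliefs would
mask the A1 phenotype. Lesion magnitudes are chosen so that every lesion
drives the rightward fixation fraction above 0.8 in the reference
simulations; all are configurable.

**Action selection** defaults to the deterministic high-precision limit
(argmax of the action posterior, ties to the lowest index), matching the
near-deterministic selection of canonical implementations of this scheme and
producing clean clinical-looking scanpaths. Posterior sampling is available
(`action_mode="sample"`) and is used where stochasticity is the point:
distributional behavioral comparisons and data generation for model
comparison.

## Lesions

`A1` multiplies the Dirichlet counts of neglected-side likelihood columns by
κ, leaving `A` unchanged (count scaling is normalization-invariant) but
erasing novelty there; uniform column scaling is used (the per-outcome
alternative is not distinguished by the behavioral consequences). `E` adds a
constant to ln E of intact-side policies (renormalized). `C2` sets
proprioceptive log-preferences to +magnitude on intact-side locations. In the
multiscale model the side predicate is evaluated on the chosen factor alone;
the A1 inflation applies to every learnable modality that depends on that
factor (a coarse lesion makes the whole left half familiar at quadrant
granularity; a fine lesion touches only fine-visual columns of left cells).
This yields the scale dissociation: coarse lesions shift the global hemifield
fraction while within-subquadrant laterality stays near-symmetric; fine
lesions do the converse. The environment is never lesioned.

## Model comparison

Candidates are replayed open loop on a recorded trial: each model receives
the recorded outcome stream, accumulates its own counts (so the A1 model's
novelty dynamics are expressed), and its actions are clamped to the data; the
log evidence is Σ_t ln q(action_t). With no free parameters this is the exact
expected log likelihood. Posteriors are a softmax over seed-averaged
evidences under a uniform model prior. Data generation for the confusion
experiment *samples* actions from the policy posterior: for sampled data the
generating model maximizes expected log evidence (Gibbs inequality), whereas
deterministic scanpaths from different lesions can coincide exactly and carry
no discriminative information.

**E/C2 equivalence.** With depth-1 policies, deterministic saccades and fixed
γ, the E lesion (+b on ln E of intact-side policies) and the C2 lesion (+b on
intact-side proprioceptive preferences, entering G through the expected-cost
term) shift ln q(π) by identical per-policy amounts up to softmax-invariant
constants. The two lesioned models are therefore behaviorally
indistinguishable, their evidences tie exactly, and their posteriors split
the abnormal probability mass equally. Breaking the tie would require a
mechanism that treats prior and preference biases asymmetrically — e.g. the
precision dynamics excluded from this package's scope.

## Reference simulation sizes

Behavioral medians use 20 seeds × 20 saccades on balanced 16-target
displays (fresh display per seed); the confusion experiment uses 40 saccades
× 10 seeds with multiscale models lesioned at the coarse scale; inference
validation uses 50 random toy models of ≤6 states and ≤3 epochs (enumeration
oracle) and 100 toys for the free-energy bound.

## What the synthetic world does and does not capture

The generator emulates the structure of a bedside cancellation task: discrete
target arrays, deterministic cancellation feedback, and fully reliable eye
position sense. It does not emulate saccadic kinematics, fixation durations,
oculomotor noise, head movement (the proprioceptive identity assumes a fixed
head), stimulus identity beyond target/non-target, or between-trial memory
(counts reset per trial). Passing tests therefore show that the *belief-level
mechanisms* produce and discriminate neglect-like search patterns under these
idealized conditions — not that real patients' scanpaths would be decoded at
this accuracy, which would additionally require estimating subject-specific
parameters and modeling sensorimotor noise.

## Known limitations

* Salience enumeration is exact but exponential in the number of modalities'
  outcome combinations; it is capped and fast-pathed for the delta
  predictions of the task models.
* Novelty uses the one-observation update per predicted state; for soft
  predictive states (not produced by the saccade models) this is the
  standard per-column approximation.
* Policy depth > 1 enumerates all action sequences and is only practical for
  toy problems.
* The E/C2 tie above is structural under fixed precision.
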