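# neglectsim

Active-inference simulation of visual neglect in the saccadic cancellation
task, with in-silico lesions and Bayesian lesion-deficit decoding.

Visual (hemispatial) neglect is a syndrome — most often after right-hemisphere
stroke — in which patients fail to explore one side of space, classically
revealed at the bedside by cancellation tasks: the patient must mark every
target in an array and leaves the left side unmarked. `neglectsim` models a
saccadic version of this task as a discrete partially observed Markov decision
process solved by active inference, and asks two questions:

1. Which *prior beliefs* would make neglect-like visual search Bayes-optimal?
   Three distinct functional lesions reproduce the syndrome.
2. Can the lesion be *decoded back* from the eye movements it produces?
   Bayesian model comparison of simulated scanpaths answers this.

It is intended for computational neuroscientists and neuropsychologists
studying attention, eye movements and lesion-deficit inference.

## The model

The agent fixates cells of an 8×8 array. Hidden states `s` are fixation
locations; 64 saccadic actions `u` each carry a deterministic transition
matrix `B(u)` whose columns are unit vectors at the destination. Outcomes have
two modalities: a visual channel with 3 outcomes — white (empty), black
(uncanceled target), red (canceled target) — whose likelihood `A1` is
parameterized by Dirichlet counts `a` (with `A_ij = a_ij / Σ_k a_kj`), and a
proprioceptive channel whose likelihood `A2` is the identity, so the agent
always knows where it is looking. Fixating a target turns it black→red, and
both observations accumulate Dirichlet counts — a synaptic short-term memory
for what has been canceled.

Policies (single saccades, re-evaluated after every fixation) are scored by
their expected free energy

```
G(π) = expected cost − salience − novelty
```

where expected cost is the cross-entropy between predicted outcomes and the
log-preferences `C` (black preferred, red unexpected), salience is the
expected state information gain (identically zero here: proprioception leaves
no state uncertainty to resolve), and novelty is the expected information gain
about the likelihood mapping — the Dirichlet KL divergence for a
one-observation update, in closed form. Policies are selected from
`P(π) = σ(ln E − γ·G(π))` with baseline prior `E` and precision `γ`.

Three lesions yield left neglect:

| lesion | mechanism | anatomical reading |
|--------|-----------|--------------------|
| `A1` | left-hemifield Dirichlet counts × κ — the left becomes familiar, so only the right is novel | disconnection of SLF II (dorsal–ventral attention networks) |
| `E`  | ln E raised for rightward saccades | putamen (habitual policy bias) |
| `C2` | preference for right-sided proprioceptive outcomes | pulvinar input to dorsal parietal cortex |

A multiscale variant encodes location by three quadtree factors (quadrant,
subquadrant, cell; 4³ = 64 locations) with color-blind target-density outcomes
at the two coarser resolutions. Lesions applied at the coarse scale produce
egocentric neglect of the array's left half; at the fine scale, allocentric
neglect of the left of every subquadrant.

## Worked example

```
$ neglectsim simulate --seed 3 --n-saccades 20 --out healthy.csv
left fixation fraction: 0.450  canceled L/R: 8/8

$ neglectsim simulate --seed 3 --n-saccades 20 --lesion A1 --out a1.csv
left fixation fraction: 0.000  canceled L/R: 0/8
```

The healthy agent splits its 20 fixations across hemifields (45% left here)
and cancels all 16 targets of the balanced array; the A1-lesioned agent never
enters the left hemifield and cancels only the 8 right-sided targets — the
cancellation-task signature of left neglect. Scanpaths are written as CSV
(`trial_id, epoch, row, col, onset_outcome, offset_outcome, model_label,
seed`) with the config hash and seed in a header comment;
`neglectsim plot` draws the scanpath over the array.

Decoding the lesion from behavior:

```
$ neglectsim confusion --seed 0 --n-saccades 40 --seeds 10
         healthy     A1      E     C2
healthy    1.000  0.000  0.000  0.000
A1         0.000  1.000  0.000  0.000
E          0.000  0.001  0.499  0.499
C2         0.000  0.001  0.499  0.499
```

Rows are the generating model, columns the decoded posterior. Health and the
A1 lesion are recovered perfectly; the E and C2 lesions are identified as
abnormal but cannot be told apart — under fixed precision γ their policy
biases are mathematically equivalent (see `docs/methods.md`).

Key configuration knobs (YAML via `--config`, see `RunConfig`): preference
strengths `c_white/c_black/c_red`, initial Dirichlet counts `e0/e1`, learning
rate `eta`, precision `gamma`, trial length `n_saccades`, lesion block
(`lesion_kind/side/magnitude/scale`), seeds.

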