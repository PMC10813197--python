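# Methods

## The problem

One hospital admission produces four kinds of evidence: demographic and
examination values recorded once (static tabular), the sectioned
admission note (static notes), laboratory values and vital signs
measured on irregular days (temporal tabular), and one ward-round note
per hospital day (temporal notes). `emrfuse` represents each modality
separately, fuses them with multimodal adaptation gates, and predicts
two binary outcomes per admission: in-hospital mortality and long stay
(length of stay > 14 days).

## Preprocessing

Temporal data are irregular and of very different lengths, so every
admission is brought onto a canonical grid before encoding:

1. **Imputation.** Per laboratory feature, linear interpolation in day
   index between observations; nearest-observation fill before the
   first and after the last; the training-cohort median for features
   never observed in an admission. Same-day duplicate measurements:
   first one wins (mirroring the first-ward-round-of-the-day rule for
   notes). A 0/1 mask records which cells were actually observed.
2. **Merge and pad.** The grid is fixed at H = 30 days. Stays beyond
   day 30 are merged into day 30: per feature the last observation at
   day >= 30 wins; notes from day 30 onward are concatenated in day
   order under a 512-token budget. Shorter stays are forward-filled
   with mask 0 and empty note slots. Forward-fill (rather than
   zero-fill) keeps per-feature scale statistics stable under padding.
3. **Windowing.** The 30-day grid is cut into n = H/W = 10
   non-overlapping consecutive windows of W = 3 days. Concatenating
   the windows reconstructs the grid exactly.
4. **Static tabular.** Continuous features are discretised against
   their reference range into low/normal/high (values exactly on a
   bound count as normal; missing counts as normal) and one-hot
   encoded; categorical features get one slot per category plus UNK.
5. **Tokenisation.** The default tokenizer splits on whitespace and is
   pluggable (any `str -> list[str]` callable); already-tokenised
   input passes through. Temporal values are z-scored with
   training-split statistics computed over observed cells only.

## Model

Four encoders produce the modality representations:

* `F_st = Onehot(I_st)` — the one-hot vector itself; projection into
  model space happens inside the gates and the day-0 projection.
* `F_sn` — a trainable token-embedding table mean-pooled over the
  static document (dimension d_note = 300; the empty document maps to
  the zero vector). A paragraph-vector model can be plugged in as an
  alternative backend.
* `F'_tt,i = ReLU(Linear(I_tt,i))`, applied per day inside window i;
  the W-day sequence runs through a 2-layer LSTM whose state is reset
  per window, and `F_tt,i` is the final hidden state.
* `F'_tn,i` — window i's note tokens contextualised by a
  segment-recurrent transformer encoder that carries a detached memory
  of the previous window's hidden states (window 1 starts empty),
  mean-pooled over tokens; the n-step `F'` sequence then runs through
  a 2-layer LSTM whose per-step outputs are `F_tn,i`.

**Multimodal adaptation gate (MAG).** With a configured primary
modality `F_p` and auxiliary `F_a`:

    g = sigmoid(W_g [F_p ; F_a] + b_g)
    H = g * (W_h F_a + b_h)
    E = F_p + alpha * H,   alpha = min(beta * ||F_p||_2 / ||H||_2, 1)

`beta` is a trainable scalar initialised uniformly on (0.5, 1.5);
`alpha` is defined as 0 when `||H|| = 0`, which removes the singularity
without changing `E`. The gate is a vector (element-wise) by default —
matching the lineage of gated multimodal fusion this operator comes
from — with a scalar mode available by configuration. One static MAG
fuses `F_sn` and `F_st` into `E_S`; one temporal MAG with parameters
shared across windows fuses each `(F_tn,i, F_tt,i)` pair into `E_i`.
The default primary modalities are the two note modalities, the
configuration reported to work best in this family of models; all four
assignments are selectable.

**Attention backtracking.** Each fused window is complemented by
scaled-dot-product attention over its strictly earlier windows:

    Q_i = E_i + sum_{j<i} softmax_j(q_i . k_j / sqrt(d)) v_j

with learned query/key/value projections, a single head, and `Q_1 =
E_1` (no history). Softmax weights at each query normalise over the
i-1 history positions. Disabling the module makes it the exact
identity — the ablation switch.

**Day-0 fusion and head.** `E_S` is projected to model width, treated
as day 0, and prepended to `Q_1..Q_n`; a 2-layer LSTM encodes the
length-(n+1) sequence and its final hidden state `Z` feeds a
linear+sigmoid head. The loss is mean binary cross-entropy with
predictions clipped to `[1e-7, 1 - 1e-7]`.

**Modality subsets.** Two-modality configurations drop the other two
encoders entirely (they are never constructed): `only_static`,
`only_time_series`, `only_tabular`, `only_notes`. When a branch has a
single modality its representation passes through un-gated.

### Readings of genuinely open design points

* The per-token transformer outputs become a window vector by mean
  pooling (length-robust; a special-position state would also work).
* The temporal-tabular LSTM runs *within* each window with per-window
  reset (the encoder is defined per window); the temporal-note LSTM
  runs *across* the window axis (its outputs are consumed
  per-window downstream).
* Backtracking attends over the fused representations `E`, and its
  history is `E` (not the already-backtracked `Q`).
* Segment memory is truncated (not back-propagated through), the
  recurrence convention of segment-level transformers.
* Relative position information enters attention as a learned
  per-head relative-offset bias (a simplification of the full
  content/position decomposition that keeps the properties that matter
  here: position-shift structure and memory compatibility).

## Numerical engine

No deep-learning framework is part of the dependency set; the layers
(LSTM, segment-recurrent transformer, attention, gates) run on a small
reverse-mode automatic-differentiation engine over numpy arrays that
is part of the package (`emrfuse._autodiff`). Default dtype is
float32; gradient checks run the engine in float64 against central
finite differences. Fully masked attention rows use a finite -1e9
score bias (never -inf), so padded windows produce finite garbage that
pooling masks away instead of NaNs.

## Training protocol

Full-scale defaults follow the standard protocol for this model
family: Adam, learning rate 1e-4, batch size 64, up to 50 epochs,
random label-stratified 8:1:1 split, checkpoint of minimum validation
loss, metrics averaged over five seeded runs (each run redraws split
and initialisation together). F1 uses threshold 0.5; no class
re-weighting or oversampling — imbalance is handled by the choice of
metrics (AUROC primary; AUPRC and F1 alongside). Stratification is a
package choice: with ~7% positives it keeps every split populated.

Two additions stabilise desk-scale optimisation and are always active:

* **Class-prior head initialisation** — the head bias starts at the
  training-split log-odds. With rare positives a 0.5-initialised head
  spends its first epochs collapsing to the base rate while large
  irrelevant gradients flow through the encoders; prior initialisation
  removes that dead phase.
* **Global gradient-norm clipping** at 1.0.

The *desk protocol* used by the benchmark experiments and tests
(`emrfuse.benchmarks`) raises the learning rate to 1.5e-3, adds
decoupled weight decay 1e-4, and trains 3-5 epochs — sized for a
single CPU core. Problem sizes: learnability on 2,000 admissions
(5 epochs), backtracking ablation on 1,000 admissions of the planted
long-range cohort (3 epochs), modality subsets on 600 admissions
(5 epochs); each over five seeds. The ablation is deliberately
evaluated at an early-training budget: the attention path exposes the
day-1..3 signal directly at the end of the sequence from the first
updates, whereas the recurrent paths must first learn to carry it —
at longer budgets the recurrent paths catch up and the architectural
contrast washes out into seed noise.

## Synthetic cohorts

Real admissions of this shape cannot be shared, so the generator
(`emrfuse.synthetic_ehr`) emulates the statistical structure the model
assumes. Defaults: 7% mortality prevalence; a per-patient geometric
length-of-stay law calibrated by bisection so P(LOS <= 14) = 0.85
(the middle of the 81-88% range typical of the cardiovascular
admission cohorts this model family is evaluated on), capped at 60
days so some stays exercise the 30-day merge; per-(day, feature)
observation probability 0.55; a 60-token artificial note vocabulary
with a mildly Zipf-like distribution, 6 tokens per daily note.

Labels come from a logistic mechanism over four planted components —
a static categorical risk factor (effect 1.5), the slope of one
laboratory feature (1.5), a designated risk token present only in the
notes of days 1-3 (2.5), and a static x slope interaction (1.0) — with
the intercept bisected to the target prevalence. Length of stay is
mildly coupled to the same risk score (coupling 0.35) so the long-stay
task is learnable, and the long-stay label is derived from the
realised stay. Effect sizes were chosen so the mechanism's own logits
rank their labels at AUROC ~0.95: strong enough for desk-scale
learnability, far from deterministic.

The *planted long-range* variant zeroes every effect except the early
note token, raises the token effect to 7.0, lowers the token base rate
to 0.2 and raises prevalence to 0.15, making token presence a
near-oracle score (AUROC >= 0.9 by construction) that is only
accessible through the first window.

What the generator does **not** emulate: natural-language structure in
notes (tokens are exchangeable draws, so nothing is learned about
syntax or context windows beyond planted tokens), inter-feature
correlation in laboratory panels, informative missingness, sub-daily
resolution, and measurement drift. Passing tests therefore demonstrate
that the architecture can extract cross-modal, trend and long-range
signal of realistic magnitude from data with realistic shape — not
clinical-grade performance on real EMR text.

## Known limitations

* The engine is single-threaded numpy; the paper-scale profile
  (12 transformer layers) is configurationally supported but not
  practical to train on one CPU core.
* The ablation contrast is small at desk scale because three recurrent
  bridges (segment memory, the note-encoder LSTM, the fusion LSTM)
  partially duplicate what backtracking provides; the direction is
  reproducible under the benchmark conditions but individual seeds can
  invert it.
* AUROC on ~60-200-record test splits carries sampling noise of
  several points; benchmark conclusions rest on seed means, not single
  runs. The subset-direction margin in particular is modest at desk
  scale and can invert on other cohorts or with fewer seeds.
* The long-stay task is close to trivial under this pipeline: the
  whole stay is windowed before prediction, so forward-filled masks
  and empty note slots after discharge make the realised stay length
  directly visible in the inputs. The task is kept for protocol
  completeness; a deployment-grade formulation would truncate inputs
  at a fixed early horizon.
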