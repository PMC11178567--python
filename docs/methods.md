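# Methods

This note documents the model, the training protocol, the synthetic data
generator and the evaluation protocol implemented in `implyseg`, together
with the numerical choices and their rationale.

## Problem setting

We want one model that segments *K* mutually exclusive foreground classes
plus background, but the training material is a collection of *complementary*
datasets: several **binary subsets** (each image annotated with a 0/1 mask
for exactly one class) and at most one **multi-class subset** (full label
maps). The mutual-exclusivity assumption — every pixel belongs to exactly
one class — lets a positive annotation of one class stand in for a negative
annotation of every other class at the same pixel. Nothing can be inferred
about other classes from a binary mask's background, so those pixels are
excluded from the loss per class.

## Label implication

`imply_from_binary` converts one binary annotation into per-class target
grids *y* and validity grids *λ*:

* annotated class *c₀*: *y = mask*, *λ = 1* everywhere (its positives and
  negatives are both known);
* every other class *c*: *λ = mask* (valid exactly where *c₀* is positive),
  *y = 0* there.

`imply_masking_only` is the ablation that drops the second rule (foreign
classes get *λ ≡ 0*): only the masking survives, and each class channel
sees its own subset only. `imply_from_multiclass` one-hot-expands a full
label map with *λ ≡ 1*, optionally with an explicit background channel.
Targets are canonically stored as 0 wherever *λ = 0* so array equality is
well defined, and every constructor records which channels were directly
annotated (the weight schemes need this to distinguish "own frame" from
"implied" counts). No background channel is ever produced for binary
samples; for the IL and EN modes background is a *decision*, made at
prediction time by the threshold fallback, not a trainable class.

## Loss

Per class the loss is a masked, positively weighted binary cross-entropy
over logits (log-sum-exp form throughout; sigmoid-then-log never appears):

    term = w_c · y · softplus(−z) + (1 − y) · softplus(z)
    L_c  = Σ term · λ  /  max(1, Σ λ)        (sums over batch and pixels)
    L    = mean of L_c over classes with at least one valid term

Normalising each class by its own count of valid terms makes the loss
reduce exactly to the standard mean BCE when *λ ≡ 1*, and leaves it
invariant under duplicating the batch. The total is the *unweighted* mean
over contributing classes so that class balance is handled solely by the
positive weights. A class whose terms are all masked contributes 0 with a
recorded term count of 0. Loss values are accumulated in float64; the
gradient (which feeds a float32 model) is computed in float32.

Three positive-weight schemes are provided:

* **neg/pos ratio** (`pos_weight_neg_pos_ratio`) — *w_c* = valid negatives /
  valid positives, counted over *λ = 1* pixels. With
  `include_implied=False` counting is restricted to each class's own
  annotated frames. A class with zero valid positives falls back to *w = 1*
  with a warning rather than an error, so degenerate subsets do not crash
  sweeps. Used by IL (including implied negatives) and per-member by EN
  (each member weighs its own class; the member's single sigmoid output
  makes a separate background weight meaningless, so none is applied).
* **softmax of negated shares** (`pos_weight_softmax_negated`) —
  *w = softmax(−share)* over all classes including background; weights sum
  to 1 and shrink with a class's share of the data. Used by FS.

## Prediction

`argmax_threshold_merge` turns a stack of per-class sigmoid maps into one
label map: the winning foreground class (ties broken deterministically to
the lowest channel index) is assigned where its probability is at least τ,
otherwise background. τ defaults to 0.5 — the natural decision boundary of
an independent sigmoid. Models trained with an explicit background channel
(FS) let background compete in the argmax directly and ignore τ. The same
rule merges an ensemble of binary models by stacking their outputs.

## Evaluation protocol

Dice is computed per image and class as 2|A∩B|/(|A|+|B|), with the
convention that a class absent from both prediction and target scores 1.0
(the model behaved as expected). Per-class scores are the mean over that
class's frames and the overall score is the mean of per-class means — a
two-level average that deliberately differs from pooling all entries.
Binary test subsets score only their own class per frame; multi-class test
subsets score all classes including background and additionally accumulate
a pixelwise confusion matrix (rows = truth, columns = prediction).

Two runs are compared with a two-sided Wilcoxon signed-rank test on the
paired (image, class) dice scores, per class and pooled. Zero differences
are dropped; if all differences are zero the result is flagged degenerate
with p = 1. For up to 25 effective pairs the exact null distribution is
computed by dynamic programming over (doubled, therefore integer) midranks
— the two-sided p is the probability of a deviation from the null mean at
least as large as observed over all 2ⁿ sign assignments; above 25 pairs the
normal approximation with continuity correction (scipy) is used.
Significance is reported at p < .05 and p < .01.

## Bundled model and optimisation

The reference model (`BlobNet`) is a small convolutional encoder–decoder:
a full-resolution 3×3 stem (width F = 8), one 2×-pooled 3×3 stage (2F), a
1×1 skip-merge back at full resolution, and a 1×1 output head. Forward and
backward passes are written directly on numpy (float32, channel-last); the
receptive field of ~10 px is enough to pool colour evidence over blob
interiors while staying fast on one CPU core (~4 ms per 64×64 image for a
full forward+backward). Any other architecture can be plugged in through
the model contract (image batch → per-class logits of the same spatial
size, plus parameter get/set).

Optimisation follows a standard protocol: AdamW (decoupled weight decay
0.1), initial learning rate 3·10⁻⁴ decayed by γ = 0.9 every 10 epochs, 100
epochs, batch size 8 — these are the `TrainConfig` defaults. The
desk-scale study overrides two of them: learning rate 3·10⁻³ and 20 epochs,
because the bundled CNN trains from scratch (no pretraining) and at 64×64
the larger step converges in minutes where the default would need an hour;
all modes share the same settings. The best epoch is selected by the
overall mean validation dice at τ, evaluated on the mode's own validation
annotations (per member for EN, whose selection therefore uses pre-merge
dice). A non-finite loss aborts the run with a diagnostic rather than
skipping batches. Two runs with identical config and seed produce
identical records; all randomness flows through counter-derived
`numpy.random.default_rng` seeds, never global state.

## Synthetic data generator

The generator emulates the *structure* of a multi-subset anatomy dataset,
not its appearance. A scene is a 64×64 RGB frame: 2–5 elliptical "organ"
blobs (semi-axes 10–55 % of the grid, the upper end giving close-up-like
frames in which one organ dominates the view) painted back-to-front over a
dark noisy background, so the label map is mutually exclusive by
construction.
Each of the 6 default classes has a mean colour; each blob adds a per-blob
colour jitter (σ = 0.04, organs vary between frames) and the frame adds
per-pixel noise (σ = 0.03). One **confusable pair** (colon /
small-intestine analogue) has its mean colours pulled halfway towards their
midpoint, so the two classes overlap visually and separating them requires
cross-class supervision — the mechanism the implied negatives provide.

From a shared pool of scenes, each class's binary subset draws
scene-disjoint frames that *contain* the class, preferring frames where its
area is large: sampling weight ∝ (area fraction)^k with k = 6·b/(1−b) for
focus bias b ∈ [0, 1) (b = 0 uniform; b ≥ 1 strict top-area selection).
The default b = 0.7 emulates the way real single-organ subsets are filmed
around their organ, which both biases each subset's viewpoint and thins out
other organs in it — the domain shift that hurts a per-class ensemble. The
multi-class subset consists of frames containing a designated centre class
(default: the stomach analogue). Desk-scale defaults: 200 train / 50 val /
50 test frames per subset, pool size 3 × total demand.

What the generator does **not** emulate: texture, lighting, specular
reflections, instruments, occlusion boundaries other than overlap, temporal
structure, and annotation noise. Passing the directional study on this
world shows the *mechanism* (implied negatives reduce cross-class confusion
and improve merged dice) — it does not predict absolute performance on real
surgical data.

## The desk-scale study

One trial = generate the world from a master seed, train IL, EN and the
masking-only ablation on it (identical hyper-parameters), evaluate on the
binary test splits (dice, per-frame own class) and on the multi-class test
split (dice incl. background + confusion matrix). A study repeats this over
three seeds and reports majority-vote orderings (IL ≥ EN, IL ≥ ablation,
IL pair-confusion ≤ EN) rather than asserting absolute numbers — the honest
scaled-down analogue of comparing mean scores on a large real dataset. The
fully supervised upper baseline is trained on the multi-class subset and
reported on its own test split. `scripts/acceptance.py` runs exactly this
study (≈15 min on one CPU core) and writes the numbers it computed.

## Known limitations

* The bundled CNN is colour/texture-level; it cannot learn shape priors or
  long-range context, so absolute dice on harder synthetic worlds saturates
  below what a large pretrained backbone would reach.
* The Bayes error of the confusable pair is nonzero by design (per-blob
  jitter is irreducible), so pair confusion never vanishes for any mode.
* On-disk masks are strict 0/255 PNGs; probabilistic or multi-label masks
  are out of scope, as are overlapping class hierarchies.
* The Wilcoxon exact path assumes exchangeable signs under the null; with
  heavy ties among |differences| midranks are used, which is standard but
  not unique.
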