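# Methods

`pestpair` implements a multi-label recognizer for predator–pest scenes:
a CNN + spatial-Transformer backbone, a label-embedding co-attention head,
and a pairwise label matching loss, together with the synthetic scene
generator used to exercise the whole pipeline end to end. This note records
the model, the generator, the parameters that matter, and the choices made
where the design was genuinely open.

## The recognition model

**Backbone.** Input scenes are square RGB images. A stack of stride-2
convolution → batch-norm → GELU stages extracts local texture features; the
final map `[B, C, H, W]` is flattened row-major into `N = H·W` patch tokens,
projected to the embedding width `d`, given learned positional codes, and
passed through pre-norm multi-head self-attention layers (the
"S-Transformer") that model long-range spatial context. Two profiles:

| profile | input | conv stages | feature map | tokens | d | heads | layers |
|---|---|---|---|---|---|---|---|
| `full` | 224×224 | 64/128/192/256 | 256×14×14 | 196 | 256 | 8 | 2 |
| `desk`  | 64×64   | 32/48/64       | 64×8×8    | 64  | 64  | 2 | 1 |

The conv widths and transformer depth in the `full` profile are the
smallest configuration reaching the 14×14×256 feature interface the
co-attention head consumes; the `desk`
profile is the CPU-scale configuration every training experiment in the
test suite uses.

**Co-attention head.** A learned label-embedding table `E ∈ R^{CL×d}`
(CL = 8 categories) plus learned per-label positional codes supplies
queries; patch tokens supply keys and values:

    Att_ij = (e_i W_Q)(f_j W_K)^T / sqrt(d)
    z_i    = Σ_j softmax_j(Att_ij) · (f_j W_V)

`z_i` passes through a two-layer MLP (hidden sizes 512 then 256 in the
full profile, i.e. 2d → d), a residual connection with `e_i`, a
squeeze-excitation channel gate (reduction 4) over the fused `CL×d` block,
and a per-label linear → sigmoid head giving presence probabilities
`p̂ ∈ [0,1]^CL`. Cross-attention is single-head by default — the score
definition has one score per label–patch pair — with a multi-head variant
behind a config flag. Label positional codes are learned because labels
have no natural order. A diagnostic `CL×CL` cosine-similarity matrix of the
fused label representations is exposed for interpretability; it carries no
training signal.

**Ablation modes.** `none` = conv features, mean-pooled, linear head;
`self` = conv + S-Transformer, mean-pooled, linear head; `co` = full model.

**Losses.** With ground-truth label set Y and candidate pair set P (all
unordered pairs by default; a predator–pest-only mode is available):

    y_ij   = 1 iff i ∈ Y and j ∈ Y
    L_pair = − Σ_{(i,j)∈P} [ y_ij log(p̂_i p̂_j) + (1−y_ij) log(1−p̂_i p̂_j) ]
    L_total = L_bce + λ·L_pair,  λ = 0.4

The printed pairwise sum is a log-likelihood (it increases with prediction
quality); the implementation returns its negation so that training
minimises it, with a flag to audit the raw sign. Products and probabilities
are clamped to `[1e-7, 1−1e-7]` before the logarithm. Both losses reduce by
summation over their terms per sample (the form the loss definitions
above prescribe, and the scale at which λ = 0.4 is meaningful) and average over the batch; a
mean-over-terms reduction is available but note that at CL = 8 it dilutes
the pair term's per-term weight to ~0.11 of a BCE term, making λ nearly
inert. With CutMix soft labels, pair indicators are taken from the hard
label set of the dominant (≥ 50% area) source, since y_ij is defined only
for hard sets.

**Training.** AdamW (weight decay 0.01), cosine-annealed learning rate,
batch size 32, optional gradient accumulation, early stopping when
validation loss fails to improve by ≥ 1e-4 for 10 consecutive epochs
(defaults; every experiment in this repository states its own epochs/lr).
The entire network and its reverse-mode differentiation are implemented in
numpy (float32), so training runs identically — and bitwise reproducibly
per seed — on any CPU.

## Metrics

Precision/recall are macro-averaged over categories (micro also reported);
**F1 is the harmonic mean of the reported precision and recall**, so the
P/R/F1 triple always satisfies the harmonic-mean identity. Per-class AP uses the
precision-at-each-positive convention over the full score ranking (no
interpolation; scikit-learn's `average_precision_score`); mAP is the
unweighted mean over classes with ≥ 1 positive, classes without positives
being excluded with a logged note. Pair-level P/R/F1 counts an image as a
pair true-positive when both member probabilities clear their thresholds
and both labels are truly present; the summary row is the arithmetic mean
over pairs. The decision threshold is 0.5 for every class (the sigmoid
midpoint).

Because the architecture has no box-regression head, IoU-threshold mAP is
reported two ways: (a) classification mAP over label rankings (primary) and
(b) an optional attention-localization mAP that derives one box per label
by thresholding the co-attention heatmap at half its maximum, taking the
largest connected component, and scoring it against ground-truth boxes at
IoU 0.5/0.75.

## Synthetic scene generator

The generator emulates the structure of a field predator–pest image
dataset: 8 glyph classes (4 predators, 4 pests) on cluttered leafy
backgrounds, with planted co-occurrence between canonical predator–prey
pairs — ladybug–aphid, lacewing–planthopper, pirate-bug–thrips,
trichogramma–corn-borer — and category frequencies shaped like the per-category image counts of the
5037-image field corpus this generator emulates.

**Presence model.** Each canonical pair is drawn from its exact 2×2 joint
table `{11: q, 10: m_i−q, 01: m_j−q, 00: 1−m_i−m_j+q}`; all other
categories are independent Bernoulli(m). Canonical pairs are disjoint, so
every entry of the implied joint matrix is exact: `q` for coupled pairs,
`m_i·m_j` elsewhere. Defaults: marginals are the emulated corpus's per-category
image-count ratios scaled ×2.5 (≈ 0.22–0.46), and each canonical
`q = 0.75·min(m_i, m_j)` — 1.5–2.6× the independence product, while every
non-canonical predator–pest joint stays strictly below the weakest
canonical joint.

**Rendering.** Glyphs are procedurally drawn ellipses/polygons with
hue-separated class colours and class-specific texture (spots, veins,
stripes); pests are small-bodied (box area < 1% of the canvas on average,
drawn from a 0.07–0.11 canvas-fraction side range) and appear in clusters
of 2–4 instances; predators are medium (0.12–0.20) with 1–2 instances.
Backgrounds carry leafy blobs and stem strokes, and a foliage blob
partially occludes one instance corner in ~40% of scenes. Boxes are
half-open `[x0,x1)×[y0,y1)` in 0-based pixels; the emitted COCO JSON uses
COCO's `[x, y, w, h]` and 1-based category ids. All randomness flows from a
single integer seed; regeneration is byte-identical.

**What passing tests do and do not show.** The glyphs are deliberately
separable — colour clutter, occlusion and scale variation are present, but
nothing approaches the inter-species visual similarity of real field
imagery. Desk-scale results therefore validate the *machinery* (losses,
attention wiring, protocols, metrics) and the *direction* of the headline
comparisons, not field-level accuracy numbers.

**Splits.** Train/validation splitting is stratified by exact label
multiset with largest-remainder rounding, so the 7:3 split is exact and
per-category prevalence is preserved (≤ 5 percentage-point divergence at
n = 1000); categories present in fewer than two images fall back to random
assignment with a warning. The unseen-pair protocol moves every image that
jointly contains a held-out pair to the test set; images with only one
member stay in train, so each species remains individually learnable while
the combination is never seen.

## Augmentation operators

* **Letterbox resize** scales by `min(H'/H, W'/W)`, centres, and pads with
  the image mean colour (avoids hard pad edges); boxes follow the same
  affine map.
* **CutMix** pastes a rectangle of image A onto B; soft labels are
  area-weighted (`λ_area·y_A + (1−λ_area)·y_B`). A union-max label mode is
  available as a config alternative. Boxes are clipped to their visible
  region and dropped below a 25% visible-fraction floor.
* **GridMask** zeroes a periodic grid of square blocks, side
  `round((1−keep)·unit)` per `unit`-sized cell at a (possibly random)
  offset; masked fraction `(1−keep)²` on divisible dimensions. Default
  keep-ratio 0.6, matching the original GridMask heuristic range.
* **Small-object boost** copies boxes under 0.5% image area (the
  32²-in-640² small-object convention), rescales, and pastes them at
  non-overlapping locations (≤ 20 attempts, skipped on failure) —
  paste-with-overwrite, not pixel addition, since additive blending
  produces non-physical artifacts.
* **Pyramid** builds aspect-preserving resized copies per scale factor
  (e.g. 0.5/1.0/1.5). No per-layer wiring into the backbone is specified
  anywhere, so the pyramid is used as multi-scale resize augmentation
  rather than as multiple network inputs.
* **Photometric/geometric jitter**: brightness scaling, random
  crop-and-resize, horizontal flip, small rotation, all driven by an
  explicit generator and hence reproducible.

## Desk-scale study conditions

All training experiments (tests and the acceptance script) use: 600
generated scenes at 64×64, split 7:3, desk profile, 12 epochs at initial
learning rate 1.5e-3 (cosine to 0), batch 32, λ = 0.4, threshold 0.5,
seeds {3, 5, 7} for replicated comparisons. These sizes were chosen once as
the smallest configuration at which every category is individually
learnable and the three directional comparisons (co-attention vs
no-attention on pair-F1; λ = 0.4 vs λ = 0; unseen-pair F1 vs a
prediction-shuffling chance baseline) are meaningful.

The unseen-pair protocol holds out the four ecologically plausible
*non-canonical* combinations (ladybug–corn-borer, lacewing–aphid,
pirate-bug–planthopper, trichogramma–thrips): canonical prey relations
stay in training with their planted structure, and the held-out
combinations — present in scenes only through independent co-presence —
are never seen jointly. Holding out several pairs is essential: with a
single held-out pair every test image contains that pair, the truth column
is constant, and row-permuting predictions provably leaves the pair
true-positive count unchanged, so the chance baseline would equal the
model. With four pairs the per-pair truth varies across the mixed test
set and the baseline is informative. The chance baseline row-permutes the
prediction matrix across images (20 permutations), preserving marginal
prediction rates while destroying image specificity.

## Numerical and degenerate-input choices

* Probability clamp 1e-7; attention softmax is max-subtracted; BCE accepts
  soft targets in [0,1].
* A pair absent from the truth everywhere has undefined recall → reported
  NaN and excluded from pair macro averages; a class with no positives has
  undefined AP → excluded from mAP with a logged note.
* Marginals of 0 or 1 are legal; all-zero marginals produce empty scenes.
* Non-finite training loss aborts with a diagnostic rather than continuing.
* Checkpoints are single-file `.npz` archives with the config embedded as
  JSON.

## Known limitations

* The renderer is stylized; no photorealism, camera metadata, or weather
  effects.
* Co-occurring glyphs are rendered conditionally independently given
  presence: when a predator and its prey share a scene, nothing about
  either glyph's appearance depends on the other. The pixels therefore
  carry essentially all per-label information, which is exactly the regime
  in which pairwise co-occurrence supervision has little to add — its
  product penalty on non-co-occurring pairs mainly biases probabilities
  downward at a fixed threshold. The benefit the pairwise loss is designed
  for (recovering a visually ambiguous member of a pair from its clearly
  visible partner) requires label-correlated ambiguity that this generator
  does not emulate, and the desk-scale λ comparison should be read with
  that in mind.
* No detection head: boxes inform the generator, augmentation and the
  optional attention-localization mAP, but the model predicts presence
  only.
* The numpy training core is single-threaded-CPU oriented; it is exact but
  not fast — the full-profile network is forward-verified, not trained,
  in the test suite.
* Pair-level evaluation uses the fixed 0.5 threshold; no per-class
  threshold estimation is implemented.
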