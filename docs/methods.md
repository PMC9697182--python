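# Methods

`drawrsa` implements a quantitative analysis of drawing-completion behaviour:
children draw freely on partially presented line drawings, and the pipeline
measures how strongly each drawing — and each child — adapts to the presented
stimulus, using crowd ratings on one track and CNN feature dissimilarities on
the other.

## The task and its stimulus design

Twelve stimuli span 4 object categories (face, house, car, human figure) x 3
presentation conditions:

* **outline** — only the object contour is shown;
* **inner** — only the characteristic inner parts (eyes, wheels, windows,
  ...) at their canonical positions;
* **scrambled** — the same inner parts with positions permuted by a
  non-identity permutation, so no canonical completion exists.

Each participant draws on one of four pre-built sets of 6 stimuli (2 per
condition, no category more than twice per set); the four sets jointly cover
every stimulus exactly twice.  Presented strokes render black, produced
strokes blue.

## The synthetic cohort (the stated world)

The generator produces the statistical structure the analysis assumes, not
visually realistic children's art.  Its two generative axes are:

* a **style mixture** over {none, scribble, trace, color, complete,
  off-target}, and
* an **adaptation probability α ∈ [0,1]**: the chance that a drawing is
  conditioned on the presented stimulus at all.  With probability 1−α the
  agent draws its fixed personal motif regardless of the stimulus (a
  top-down-dominated drawer); the recorded ground-truth style then describes
  what is actually on the canvas (`off_target`).

Conditioned drawings realise the sampled style: *complete* adds the
complementary template strokes (inner parts for an outline stimulus, the
outline otherwise), *trace* re-draws the presented strokes with 4 px jitter,
*color* hatches the presented region, *scribble* places 5–30 short random
polylines, biased toward the stimulus bounding box with probability α per
stroke.  `none` leaves the canvas empty.

Age trends are logistic in months.  Defaults: completion weight
`sigmoid(0.12·(age−48))`, with the remaining mass split in fixed proportions
(scribble 0.40, trace 0.20, color 0.20, off-target 0.13, none 0.07); mean α
runs from 0.15 to 0.97 with the same midpoint and slope, and per-child α is
Beta-distributed (concentration 12) around that mean.  Per-child mixture
variability is Dirichlet (concentration 60).  The midpoint of 48 months and
the steep slopes encode two qualitative facts the analysis is expected to
reproduce: scribbling is largely replaced by completion during the fifth
year, and the oldest children (>67 months) behave almost adult-like, so
their group RDM should be statistically indistinguishable from the adults'.
A flatter calibration (completion still <80% at 6 years) leaves a systematic
level gap between the oldest group RDM and the adult RDM that no amount of
desk-scale sampling noise covers — with it, the oldest group would test as
significantly different from adults, contradicting the qualitative pattern
being modelled.  This is a deliberate simplification: in real cohorts
tracing and colouring persist at all ages at low rates.

Adults are pure completers (α = 1) with 2 px motor jitter; 5 adults draw
every stimulus twice (120 drawings — the deterministic upper bound of the
"up to two times per stimulus" collection rule).

Raters score seven statements (s1/s2 completion, s3/s4 scribbling, s5
tracing, s6 coloring, s7 relatedness) around style-conditional means (85 for
statements matching the drawn style, 10 otherwise; relatedness is high for
complete/trace/color), plus Gaussian noise (default sd 8) clipped to
[0, 100], and guess the presented category correctly with probability 0.85
by default.  AQ sheets have 50 binary items with per-item endorsement
probability drawn from Beta(2, 4) per child (population mean ≈ 17/50) and
2% missingness.

**What a green test does and does not establish.**  The generator's world is
deterministic templates plus parametric noise: recovery tests establish that
the pipeline's machinery (preprocessing, feature extraction, RDM algebra,
statistics) transmits the generative signal faithfully.  They do not
establish that the CNN features capture what matters in real children's
drawings — stroke quality, pressure, partial completions, and semantic
content are all outside the stated world.

## Image processing

512×512 canvas, 3 px stroke width (wide enough to survive downsampling to
224).  Preprocessing follows the standard VGG recipe: bilinear resize to
224×224, per-channel mean subtraction (123.68, 116.779, 103.939).  Blue ink
is recolored to black before feature extraction (exact RGB match for
synthetic data; a channel-dominance rule is available for scans).  Two image
variants feed the network:

* **full drawing** (presented + produced, recolored) — used when two
  drawings on the *same* stimulus are compared (child vs adult), because the
  presented part is shared;
* **produced-only** (produced layer re-rendered alone, recolored) — used
  when drawings on *different* stimuli are compared (group and per-child
  RDMs), so the presented part cannot drive the distances.  Removal happens
  at the stroke level, avoiding halo artifacts where strokes cross.

## Backbones

All analyses address seven named layers — pool1–pool5, fc6, fc7 — mapped by
adapters onto a concrete network.  The default is a seed-deterministic
random-weight VGG-style network (5 conv+pool blocks with 8–16 channels, two
64-unit fully connected layers, features taken after each ReLU).  Random
convolutional features preserve enough image structure for
relative-dissimilarity analyses while keeping the pipeline offline and fast;
they are *not* a substitute for pretrained features when semantic content
matters.  An ImageNet-pretrained VGG19 adapter (fc6/fc7 = the 4096-unit
fully connected layers) provides the same interface when torch/torchvision
and weights are available; otherwise it raises a named error pointing at the
test backbone.

## Dissimilarity and RDMs

The distance between two feature vectors is the Pearson correlation
distance

    d(x, y) = 1 − cov(x, y) / √(var(x)·var(y))  ∈ [0, 2].

Covariance and variance use the population convention (the ratio is
convention-invariant).  Constant vectors make the correlation undefined; the
total convention used here is d = 0 if both vectors are constant and equal
(identical images, e.g. two empty drawings) and d = 2 otherwise, with a
warning — empty drawings are legitimately fed through the network, so the
function must be total.

* **Group RDM**: per stimulus, average the produced-only feature vectors of
  one age group, then take pairwise distances between the 12 averages
  (average-then-distance).
* **Per-child RDM**: 6×6 distances between the child's produced-only
  drawings; requires the complete 6-stimulus set (children with fewer are
  excluded and logged).  Default layer fc7, the most global representation.
* **RDM score**: mean off-diagonal entry.  0 for a child who repeats one
  motif; high for a child whose drawings track the stimuli.  The score
  saturates at high α, because canonical completions of related stimuli
  (e.g. the outlines completing a category's inner and scrambled versions)
  resemble each other; the α → score mapping is steep near 0 and flat near
  1, which is why cohort-level recovery correlations sit near 0.4 rather
  than 0.9.
* **Block contrast** (recovery metric): mean between-category minus mean
  within-category off-diagonal distance; positive values mean same-category
  stimuli cluster, the signature of adaptive drawing.

## Ratings and questionnaire rules

* Rater QC: a rater's records survive only if their known-answer accuracy is
  **strictly above** 70% (configurable).
* Aggregation: statements are averaged within rater, then across raters
  (each rater weighs equally), then paired statements merge into the
  completion and scribbling scores.  Drawings known to be empty are forced
  to 0 on every score.  Drawings with no surviving raters are reported
  missing rather than imputed; drawings with few raters keep an
  `n_raters_used` count.
* Style sets: drawings whose average style rating is **strictly above** the
  cutoff (default 70; 60/70/80 supported for robustness checks).
* AQ: 50 binary items; scored iff ≥40 answered; scaled by 50/n_answered.
  The ≥32 flag is reported, never used as a filter.
* Dominant style per child: argmax of the child-mean style scores, ties
  broken completion > scribbling > tracing > coloring (logged).

## Statistics

* **Age groups**: ≤44, 45–58, 59–67, >67 months (chosen to balance drawing
  counts in the original design).
* **Mixed-model LRT**: nested linear mixed models fit by maximum likelihood
  (not REML — required for valid fixed-effect LRTs); χ² = 2·Δloglik clamped
  at 0, df = fixed-parameter difference.  One random term maps to a grouped
  random intercept; several random terms become crossed variance components
  on a trivial all-data group.  The default optimizer is cross-checked
  against a Powell refit and the better likelihood kept, because the
  variance-component parameterisation is prone to poor local optima.  A test
  term constant in the data returns χ²=0, p=1 with a warning instead of
  fitting a singular design.
* **Group-vs-adult RDM comparison**: the entries of two RDMs over the same
  stimuli are paired; the statistic is the absolute mean of the paired
  differences and the null is simulated by random sign flips
  (plus-one p-value, never below 1/(n_perm+1)).  A sign-flip test is used
  because RDM entries are mutually dependent, which invalidates two-sample
  t-tests; no correction is applied across the four age groups, and the
  output flags this.
* **RDM score vs completion score**: Pearson correlation with the two-sided
  t-transform p-value on n−2 df.

## Numerical and engineering choices

* One master seed drives everything; per-stage generators are derived from
  it, so the pipeline is byte-deterministic (two runs with the same config
  produce identical CSVs).
* Feature extraction caches per content-digest of the stroke geometry (ids
  alone are not unique across cohorts) and retains only the requested layer
  plus fc6/fc7, keeping memory flat on large cohorts; cached activations are
  stored as float32.
* The pipeline has no stage-level cache/resume: at desk scale a full rerun
  is cheaper than cache invalidation logic.
* RDM validity (symmetry 1e-9, zero diagonal, range [0, 2]) is asserted on
  every matrix the pipeline writes.

## Known limitations

* Random-weight features are weaker than pretrained ones at separating
  semantically different but texturally similar drawings; conclusions about
  real drawings require the VGG19 route.
* The adult model is homogeneous (jittered canonical completions); real
  adult drawings vary in style, which would soften adult RDM structure.
* The rating model treats statements as conditionally independent given the
  drawn style; real raters show halo effects and idiosyncratic scales.
* Group RDMs on small cohorts may miss stimuli in some age groups; the
  pipeline then restricts all matrices to the common label subset before
  comparison.
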