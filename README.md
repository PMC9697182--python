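# drawrsa

Representational similarity analysis (RSA) of drawing-completion behaviour.

Children who are shown a partial line drawing — the outline of a face, the
inner features of a car — complete it in ways that change systematically
with development: young children scribble or repeat a favourite motif, older
children complete the stimulus the way adults do.  `drawrsa` quantifies this
with two complementary pipelines on the same drawings:

1. **Crowd ratings.**  Raters score each drawing on seven statements (0–100)
   covering completion, scribbling, tracing and colouring, plus a
   known-answer check of what the presented stimulus was.  Raters at or
   below 70% known-answer accuracy are dropped; statement scores aggregate
   into per-drawing style scores, and empty drawings score 0.
2. **CNN features.**  Each drawing (blue ink recolored black, resized to
   224×224, mean-subtracted) is passed through a VGG-style network, and
   activations of the five pooling and two fully connected layers serve as
   feature vectors.  The dissimilarity between drawings *i* and *j* is the
   Pearson correlation distance

       d(x_i, x_j) = 1 − cov(x_i, x_j) / √(var(x_i)·var(x_j)) ∈ [0, 2].

   Distances over labelled stimuli form representational dissimilarity
   matrices (RDMs): 12×12 matrices of average-feature distances per age
   group, and 6×6 per-child matrices whose mean off-diagonal entry — the
   **RDM score** — measures how strongly a child adapted their drawing to
   the presented stimulus (0 = drew the same thing everywhere).

Because the original museum cohort is not bundled, the package ships a
first-class synthetic cohort generator whose agents have a ground-truth
adaptation probability α and age-dependent style mixtures, so every stage is
testable end to end: the per-child RDM score recovers α, group RDM block
structure strengthens with age, and rated completion correlates with the
RDM score — the directions the method is designed to detect.

## Worked example

```python
import numpy as np
from drawrsa import FeatureExtractor, make_test_backbone, simulate_cohort, simulate_drawing
from drawrsa.cohort import ChildAgent, STYLES
from drawrsa.rsa import child_rdm, rdm_score

net = make_test_backbone(seed=0)
extractor = FeatureExtractor(net)
bundle = simulate_cohort(1, rng=np.random.default_rng(0))
stimuli = [d.stimulus for d in bundle.drawings[:6]]

weights = {s: 0.0 for s in STYLES} | {"complete": 1.0}
for alpha in (0.0, 0.3, 0.9):
    agent = ChildAgent("demo", 60, alpha, weights, motif_seed=1, aq_propensity=0.3)
    rng = np.random.default_rng(1000)
    drawings = [simulate_drawing(agent, s, rng, f"demo-{i}") for i, s in enumerate(stimuli)]
    print(alpha, round(rdm_score(child_rdm(drawings, extractor, layer="fc7")), 4))
```

Averaged over 12 simulated children per level (`examples/03_features_and_rdms.py`):

```
mean RDM score over 12 simulated children per adaptation level:
  alpha = 0.0: 0.0000
  alpha = 0.3: 0.0946
  alpha = 0.9: 0.1168
```

An α=0 agent repeats its motif on all six stimuli, so all pairwise feature
distances — and the score — are 0; adaptive agents draw differently on each
stimulus and score high.  At cohort level (`examples/05_age_groups_and_stats.py`,
100 children):

```
group   n_children   block_contrast   p (vs adults, 1000 sign-flips)
  1           25          -0.0034        0.0010
  2           13           0.0067        0.0010
  3           14           0.0260        0.0030
  4           48           0.0377        0.1049
adult        5           0.0301

age effect on completion score: chi2(1) = 157.58, p = 3.83e-36
RDM score vs completion score: r(98) = 0.27, p = 0.0059
```

Block contrast (between-category minus within-category RDM distance) grows
with age: older children cluster their drawings by stimulus category the way
adults do, and only the oldest group is statistically indistinguishable from
the adult RDM.  The mixed-model likelihood-ratio test detects the age effect
on the crowd-rated completion score, and the RDM score tracks that score.

The `examples/` directory holds one short script per capability: cohort
simulation, rating aggregation and AQ scoring, features and RDMs,
style-vs-adult distances, age-group statistics, and the full pipeline
(`run_pipeline`), which writes every table (scores, style sets, distance
summaries, five RDMs, LRT results, permutation p-values, correlation, run
manifest) into one output directory, byte-reproducibly per seed.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the full pipeline on a synthetic cohort (24 children, 500-permutation
tests) as an end-to-end smoke check and writes the result JSON to `--out`.
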