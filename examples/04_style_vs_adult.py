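"""Style sets and their distance to adult drawings, per network layer.

Drawings whose average style rating exceeds 70 form one set per style.  Each
set's drawings are compared (as full drawings, since child and adult share
the presented part) to all adult drawings on the same stimulus.  Completed
drawings are expected to sit closest to the adults, especially at fc7.
"""
import numpy as np

from drawrsa import FeatureExtractor, make_test_backbone, simulate_cohort
from drawrsa.ratings import aggregate_drawing_scores, qc_filter_raters
from drawrsa.rsa import select_style_sets, style_vs_adult_distances

bundle = simulate_cohort(n_children=30, rng=np.random.default_rng(101))
filtered = qc_filter_raters(bundle.ratings, bundle.stimulus_truth)
table = aggregate_drawing_scores(filtered, bundle.empty_drawing_ids)
sets = select_style_sets(table, cutoff=70.0)
print("style-set sizes at cutoff 70:",
      {style: len(s) for style, s in sets.items()})

extractor = FeatureExtractor(make_test_backbone(0))
child_drawings = {d.drawing_id: d for d in bundle.drawings}

print(f"\n{'style':<12}" + "".join(f"{layer:>9}" for layer in ("pool1", "fc6", "fc7")))
for style, sset in sets.items():
    if not len(sset):
        continue
    row = [
        style_vs_adult_distances(sset, child_drawings, bundle.adult_drawings,
                                 extractor, layer).mean
        for layer in ("pool1", "fc6", "fc7")
    ]
    print(f"{style:<12}" + "".join(f"{v:>9.4f}" for v in row))

print("\nSmaller numbers mean closer to adult drawings.  The completion set "
      "should have the smallest fc7 distance: completed drawings look like "
      "adult completions at the global-feature level.")
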