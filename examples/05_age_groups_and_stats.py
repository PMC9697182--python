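"""Age-group RDMs, developmental contrasts, and the statistical stages.

Children are split into four age groups (<=44, 45-58, 59-67, >67 months).
Per group, features of produced-only drawings are averaged per stimulus and
a 12x12 RDM is computed; its category block contrast rises with age, and a
paired sign-flip permutation test compares each group RDM to the adult RDM.
A mixed-model likelihood-ratio test checks the age effect on the completion
score, and the per-child RDM score is correlated with the completion score.
"""
import warnings

import numpy as np

from drawrsa import FeatureExtractor, make_test_backbone, simulate_cohort
from drawrsa.analysis import (
    assign_age_groups,
    compare_group_to_adult_rdm,
    correlate_rdm_completion,
    lrt_fixed_effect,
)
from drawrsa.ratings import aggregate_drawing_scores, qc_filter_raters
from drawrsa.rsa import block_contrast, child_rdm, group_rdm, rdm_score
from drawrsa.pipeline import _common_label_subset

bundle = simulate_cohort(n_children=100, rng=np.random.default_rng(7))
extractor = FeatureExtractor(make_test_backbone(0))

groups = {a.child_id: a.group for a in assign_age_groups(bundle.children)}
feats = {g: {} for g in (1, 2, 3, 4)}
for d in bundle.drawings:
    feats[groups[d.child_id]].setdefault(d.stimulus.label, []).append(
        extractor.features(d, "fc7", produced_only=True)
    )
adult_feats = {}
for d in bundle.adult_drawings:
    adult_feats.setdefault(d.stimulus.label, []).append(
        extractor.features(d, "fc7", produced_only=True)
    )
rdms = {g: group_rdm(dict(sorted(f.items()))) for g, f in feats.items()}
rdms["adult"] = group_rdm(dict(sorted(adult_feats.items())))
rdms = _common_label_subset(rdms)

category = lambda lbl: lbl.split(":")[0]
rng = np.random.default_rng(5)
print("group   n_children   block_contrast   p (vs adults, 1000 sign-flips)")
for g in (1, 2, 3, 4):
    n = sum(1 for v in groups.values() if v == g)
    c = block_contrast(rdms[g], category)
    p = compare_group_to_adult_rdm(rdms[g], rdms["adult"], n_perm=1000, rng=rng)
    print(f"  {g}          {n:3d}         {c:8.4f}        {p:.4f}")
print(f"adult        5         {block_contrast(rdms['adult'], category):8.4f}")

filtered = qc_filter_raters(bundle.ratings, bundle.stimulus_truth)
table = aggregate_drawing_scores(filtered, bundle.empty_drawing_ids)
rows = bundle.metadata().merge(table, on="drawing_id")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = lrt_fixed_effect(rows, "completion", ["age_months"], "age_months",
                           ["child_id", "category", "condition"])
print(f"\nage effect on completion score: chi2({res.df}) = {res.chi2:.2f}, p = {res.p:.2e}")

by_child = bundle.drawings_by_child()
scores, comps = [], []
for agent in bundle.children:
    scores.append(rdm_score(child_rdm(by_child[agent.child_id], extractor)))
    ids = [d.drawing_id for d in by_child[agent.child_id]]
    comps.append(table[table["drawing_id"].isin(ids)]["completion"].mean())
corr = correlate_rdm_completion(scores, comps)
print(f"RDM score vs completion score: r({corr.df}) = {corr.r:.2f}, p = {corr.p:.4f}")
print("\nYoung groups differ sharply from adults (tiny p); the oldest group "
      "does not.  The RDM score tracks the crowd-rated completion score.")
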