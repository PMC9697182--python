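"""Crowd-rating aggregation with quality control, plus AQ questionnaire scoring.

Raters score seven statements (0-100) per drawing and guess the presented
category; raters at or below 70% guess accuracy are dropped.  Statement
scores aggregate into per-drawing completion/scribbling/tracing/coloring
scores, and empty drawings are forced to 0.  AQ sheets are scored when at
least 40 of 50 items were answered, rescaled to the 50-item equivalent.
"""
import numpy as np

from drawrsa import simulate_cohort
from drawrsa.ratings import (
    aggregate_drawing_scores,
    compute_aq,
    dominant_style,
    qc_filter_raters,
    rater_accuracies,
)

bundle = simulate_cohort(n_children=40, rng=np.random.default_rng(0))

acc = rater_accuracies(bundle.ratings, bundle.stimulus_truth)
filtered = qc_filter_raters(bundle.ratings, bundle.stimulus_truth, threshold=0.7)
print(f"raters: {acc.size}, surviving QC (>70% correct guesses): "
      f"{filtered['rater_id'].nunique()}")

table = aggregate_drawing_scores(filtered, bundle.empty_drawing_ids)
print(f"\nscore table: {len(table)} drawings; first rows:")
print(table.head(4).round(1).to_string(index=False))

child0 = bundle.children[0]
ids = [d.drawing_id for d in bundle.drawings_by_child()[child0.child_id]]
print(f"\ndominant style of {child0.child_id} (age {child0.age_months} mo, "
      f"alpha {child0.alpha:.2f}): {dominant_style(table, ids)}")

row = bundle.aq_sheets.iloc[0]
aq = compute_aq(row[[f"item_{i}" for i in range(1, 51)]], child_id=row["child_id"])
print(f"\nAQ for {aq.child_id}: {aq.n_answered}/50 items answered, raw sum "
      f"{aq.raw_sum}, scaled score {aq.scaled_score:.1f} "
      f"(scaled by 50/n_answered; missing if < 40 answered)")
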