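"""Crowd-rating aggregation, rater quality control, and AQ questionnaire scoring.

Raters score seven statements (s1/s2 completion, s3/s4 scribbling, s5
tracing, s6 coloring, s7 relatedness) on a 0-100 scale, plus a known-answer
guess of the presented object's category.  A rater survives QC only if their
guess accuracy is strictly above the threshold.  Statement scores are
averaged within rater, then across raters, so each rater carries equal
weight.  Drawings known to be empty get 0 on every score regardless of what
raters said.

The AQ questionnaire has 50 binary items; a sheet is scored only when at
least 40 items were answered, in which case the raw sum is rescaled to the
full 50-item equivalent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STATEMENT_COLUMNS",
    "AQResult",
    "qc_filter_raters",
    "rater_accuracies",
    "aggregate_drawing_scores",
    "compute_aq",
    "dominant_style",
]

logger = logging.getLogger(__name__)

STATEMENT_COLUMNS = ("s1", "s2", "s3", "s4", "s5", "s6", "s7")
STYLE_STATEMENTS = {
    "completion": ("s1", "s2"),
    "scribbling": ("s3", "s4"),
    "tracing": ("s5",),
    "coloring": ("s6",),
    "relatedness": ("s7",),
}
STYLE_TIE_ORDER = ("completion", "scribbling", "tracing", "coloring")

AQ_N_ITEMS = 50
AQ_MIN_ANSWERED = 40
AQ_CUTOFF = 32


@dataclass(frozen=True)
class AQResult:
    child_id: str
    n_answered: int
    raw_sum: int
    scaled_score: float | None

    @property
    def above_cutoff(self) -> bool | None:
        """Flag only — never used as a filter."""
        if self.scaled_score is None:
            return None
        return self.scaled_score >= AQ_CUTOFF


def rater_accuracies(records: pd.DataFrame, stimulus_truth: dict) -> pd.Series:
    """Known-answer guess accuracy per rater."""
    truth = records["drawing_id"].map(stimulus_truth)
    if truth.isna().any():
        missing = records.loc[truth.isna(), "drawing_id"].unique()[:5]
        raise KeyError(f"no known category for drawings {list(missing)}")
    correct = (records["guess"] == truth).astype(float)
    return correct.groupby(records["rater_id"]).mean()


def qc_filter_raters(
    records: pd.DataFrame, stimulus_truth: dict, threshold: float = 0.7
) -> pd.DataFrame:
    """Drop all records of raters whose guess accuracy is <= threshold
    (strictly-greater-than survives)."""
    acc = rater_accuracies(records, stimulus_truth)
    keep = acc[acc > threshold].index
    dropped = sorted(set(acc.index) - set(keep))
    if dropped:
        logger.info("QC removed %d raters: %s", len(dropped), dropped)
    return records[records["rater_id"].isin(keep)].reset_index(drop=True)


def aggregate_drawing_scores(
    records: pd.DataFrame, empty_drawings: set = frozenset()
) -> pd.DataFrame:
    """Per-drawing style scores: average each statement within rater, then
    across raters, then average the paired statements into the completion and
    scribbling scores.  Empty drawings score 0 everywhere.

    Returns a DataFrame with drawing_id, completion, scribbling, tracing,
    coloring, relatedness, n_raters_used.
    """
    rows = []
    rated_ids = set()
    if len(records):
        for drawing_id, grp in records.groupby("drawing_id", sort=True):
            rated_ids.add(drawing_id)
            if drawing_id in empty_drawings:
                continue
            stmt_means = grp[list(STATEMENT_COLUMNS)].mean(axis=0)
            row = {"drawing_id": drawing_id, "n_raters_used": int(grp["rater_id"].nunique())}
            for style, stmts in STYLE_STATEMENTS.items():
                row[style] = float(np.mean([stmt_means[s] for s in stmts]))
            rows.append(row)
    for drawing_id in sorted(empty_drawings):
        row = {"drawing_id": drawing_id, "n_raters_used": 0}
        row.update({style: 0.0 for style in STYLE_STATEMENTS})
        rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=["drawing_id", "completion", "scribbling", "tracing", "coloring",
                 "relatedness", "n_raters_used"],
    )
    return out.sort_values("drawing_id").reset_index(drop=True)


def compute_aq(answers, child_id: str = "") -> AQResult:
    """Score one 50-item AQ sheet (values 0, 1, or missing)."""
    arr = np.asarray(pd.Series(answers, dtype="float64"))
    if arr.size != AQ_N_ITEMS:
        raise ValueError(f"AQ sheet must have {AQ_N_ITEMS} items, got {arr.size}")
    answered = ~np.isnan(arr)
    vals = arr[answered]
    if not np.all(np.isin(vals, (0.0, 1.0))):
        bad = sorted(set(vals) - {0.0, 1.0})
        raise ValueError(f"AQ items must be 0/1/missing; found {bad}")
    n_answered = int(answered.sum())
    raw = int(vals.sum())
    if n_answered >= AQ_MIN_ANSWERED:
        scaled = raw * AQ_N_ITEMS / n_answered
    else:
        scaled = None
    return AQResult(child_id, n_answered, raw, scaled)


def dominant_style(score_table: pd.DataFrame, drawing_ids) -> str | None:
    """The style with the maximum child-level mean score across the child's
    scored drawings; ties break in the fixed order completion > scribbling >
    tracing > coloring."""
    sub = score_table[score_table["drawing_id"].isin(set(drawing_ids))]
    if sub.empty:
        return None
    means = {style: float(sub[style].mean()) for style in STYLE_TIE_ORDER}
    best = max(means.values())
    winners = [s for s in STYLE_TIE_ORDER if means[s] == best]
    if len(winners) > 1:
        logger.info("dominant_style tie between %s; using %s", winners, winners[0])
    return winners[0]
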