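"""Representational dissimilarity analysis of drawing features.

The dissimilarity between two feature vectors is the Pearson correlation
distance

    d(x, y) = 1 - cov(x, y) / sqrt(var(x) * var(y)),

which lies in [0, 2] and is invariant to affine rescaling of either vector.
RDMs collect these distances over labelled stimuli; the per-child *RDM score*
(mean off-diagonal entry of a child's 6x6 RDM) quantifies how strongly the
child adapted their drawing to the presented stimulus — a repetitive drawer
produces near-identical images and a score near 0, an adaptive drawer
produces diverse images and a high score.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import FeatureExtractor, FeatureVector

__all__ = [
    "RDM",
    "StyleSet",
    "DistanceSummary",
    "ZeroVarianceWarning",
    "MissingLabelError",
    "pearson_distance",
    "group_rdm",
    "child_rdm",
    "rdm_score",
    "select_style_sets",
    "style_vs_adult_distances",
    "block_contrast",
]

RATED_STYLES = ("completion", "scribbling", "tracing", "coloring")


class ZeroVarianceWarning(UserWarning):
    pass


class MissingLabelError(ValueError):
    pass


@dataclass(frozen=True)
class RDM:
    matrix: np.ndarray
    labels: tuple
    layer: str = "fc7"
    produced_only: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        labels = tuple(self.labels)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(labels):
            raise ValueError("RDM matrix must be square and match its labels")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=tol, rtol=0.0):
            raise ValueError("RDM is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=tol):
            raise ValueError("RDM diagonal is not zero")
        if m.min() < -tol or m.max() > 2.0 + tol:
            raise ValueError("RDM entries outside [0, 2]")

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle entries (each unordered pair once)."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def to_csv(self, path) -> None:
        path = Path(path)
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(path)
        sidecar = {"layer": self.layer, "produced_only": self.produced_only,
                   "labels": list(self.labels)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "RDM":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(df.to_numpy(), tuple(df.index), meta["layer"], meta["produced_only"])


@dataclass(frozen=True)
class StyleSet:
    style: str
    drawing_ids: tuple
    cutoff: float

    def __len__(self) -> int:
        return len(self.drawing_ids)


@dataclass(frozen=True)
class DistanceSummary:
    style: str
    layer: str
    per_drawing_distances: tuple
    skipped: tuple = ()

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_drawing_distances))

    @property
    def sd(self) -> float:
        d = np.asarray(self.per_drawing_distances)
        return float(d.std(ddof=1)) if d.size > 1 else 0.0


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=np.float64).ravel()


def pearson_distance(x, y) -> float:
    """Pearson correlation distance, total on constant vectors.

    Constant inputs make the correlation undefined; the convention here is
    d = 0 when both vectors are constant and equal (identical images) and
    d = 2 otherwise, with a warning.  cov/var use the population convention;
    the ratio is convention-invariant.
    """
    if isinstance(x, FeatureVector) and isinstance(y, FeatureVector):
        if x.layer != y.layer:
            raise ValueError(f"layer mismatch: {x.layer!r} vs {y.layer!r}")
    xv, yv = _values(x), _values(y)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 2:
        raise ValueError("vectors must have length >= 2")

    x_const = np.all(xv == xv[0])
    y_const = np.all(yv == yv[0])
    if x_const or y_const:
        warnings.warn(
            "Pearson distance on constant feature vector(s); using total-distance convention",
            ZeroVarianceWarning,
            stacklevel=2,
        )
        return 0.0 if (x_const and y_const and xv[0] == yv[0]) else 2.0

    # exact-identity fast paths: d(x, x) = 0 and d(x, -x) = 2 hold mathematically
    if np.array_equal(xv, yv):
        return 0.0
    if np.array_equal(xv, -yv):
        return 2.0

    xc = xv - xv.mean()
    yc = yv - yv.mean()
    vx, vy = float(xc @ xc), float(yc @ yc)
    if vx == 0.0 or vy == 0.0:  # numerically constant (underflow of tiny values)
        warnings.warn(
            "Pearson distance on numerically constant feature vector(s)",
            ZeroVarianceWarning,
            stacklevel=2,
        )
        return 2.0
    r = float(xc @ yc / np.sqrt(vx * vy))
    return float(np.clip(1.0 - r, 0.0, 2.0))


def _distance_matrix(vectors: list, labels, layer: str, produced_only: bool) -> RDM:
    n = len(vectors)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pearson_distance(vectors[i], vectors[j])
            m[i, j] = m[j, i] = d
    return RDM(m, tuple(labels), layer, produced_only)


def group_rdm(features: dict, layer: str = "fc7", produced_only: bool = True) -> RDM:
    """Average-then-distance RDM: per stimulus label, average the feature
    vectors, then take pairwise Pearson distances between the averages.
    With the full design present this is the 12x12 stimulus RDM."""
    labels = list(features.keys())
    means = []
    for label in labels:
        vecs = [_values(v) for v in features[label]]
        if not vecs:
            raise MissingLabelError(f"no feature vectors for stimulus {label!r}")
        means.append(np.mean(np.stack(vecs), axis=0))
    return _distance_matrix(means, labels, layer, produced_only)


def child_rdm(drawings: list, extractor: FeatureExtractor, layer: str = "fc7",
              expected_n: int = 6) -> RDM:
    """One child's RDM over the stimuli they drew on, from produced-only
    images.  Requires the complete set (default 6 distinct stimuli); callers
    exclude and log children with fewer drawings."""
    if len(drawings) < expected_n:
        raise ValueError(
            f"child {drawings[0].child_id if drawings else '?'} has {len(drawings)} "
            f"drawings; the complete set of {expected_n} is required"
        )
    ordered = sorted(drawings, key=lambda d: d.stimulus.label)
    labels = [d.stimulus.label for d in ordered]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate stimulus labels within one child's set")
    with warnings.catch_warnings():
        # empty (all-white) drawings legitimately yield constant activations
        warnings.simplefilter("ignore", ZeroVarianceWarning)
        vectors = [extractor.features(d, layer, produced_only=True) for d in ordered]
        return _distance_matrix(vectors, labels, layer, produced_only=True)


def rdm_score(rdm: RDM) -> float:
    """Mean of the RDM's off-diagonal entries: the stimulus-adaptation score."""
    if rdm.n < 2:
        raise ValueError("RDM score needs n >= 2")
    return float(np.mean(rdm.off_diagonal()))


def select_style_sets(score_table: pd.DataFrame, cutoff: float = 70.0) -> dict:
    """Drawings whose average style rating strictly exceeds the cutoff, per
    style.  Empty sets are returned empty (the caller may log them)."""
    sets = {}
    for style in RATED_STYLES:
        mask = score_table[style] > cutoff
        ids = tuple(score_table.loc[mask, "drawing_id"])
        sets[style] = StyleSet(style, ids, cutoff)
    return sets


def style_vs_adult_distances(
    style_set: StyleSet,
    child_drawings: dict,
    adult_drawings: list,
    extractor: FeatureExtractor,
    layer: str = "fc7",
) -> DistanceSummary:
    """Per drawing in the style set: mean Pearson distance to all adult
    drawings on the same stimulus, using FULL drawings (presented + produced,
    recolored) because both share the presented part.  Drawings on stimuli no
    adult drew are skipped and reported."""
    adults_by_label: dict = {}
    for a in adult_drawings:
        adults_by_label.setdefault(a.stimulus.label, []).append(a)
    adult_feats = {
        label: [extractor.features(a, layer, produced_only=False) for a in group]
        for label, group in adults_by_label.items()
    }
    dists = []
    skipped = []
    for did in style_set.drawing_ids:
        d = child_drawings[did]
        label = d.stimulus.label
        if label not in adult_feats:
            skipped.append(did)
            continue
        f = extractor.features(d, layer, produced_only=False)
        dists.append(float(np.mean([pearson_distance(f, af) for af in adult_feats[label]])))
    return DistanceSummary(style_set.style, layer, tuple(dists), tuple(skipped))


def block_contrast(rdm: RDM, category_of_label) -> float:
    """Mean between-category minus mean within-category off-diagonal distance:
    positive when same-category stimuli cluster (the signature of
    stimulus-adaptive drawing)."""
    if callable(category_of_label):
        cats = [category_of_label(lbl) for lbl in rdm.labels]
    else:
        cats = [category_of_label[lbl] for lbl in rdm.labels]
    if len(set(cats)) < 2:
        raise ValueError("block contrast needs at least 2 categories")
    within, between = [], []
    for i in range(rdm.n):
        for j in range(i + 1, rdm.n):
            (within if cats[i] == cats[j] else between).append(rdm.matrix[i, j])
    if not within:
        raise ValueError("no within-category pairs in this RDM")
    return float(np.mean(between) - np.mean(within))
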