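"""Completion-task stimuli: 4 object categories x 3 presentation conditions.

Each stimulus is a partial line drawing.  In the *outline* condition only the
object contour is shown; in the *inner* condition only the characteristic
inner parts (eyes, wheels, windows, ...) appear at their canonical positions;
in the *scrambled* condition the same inner parts appear with their positions
permuted by a non-identity permutation, so the canonical completion is not
available.  Templates are hand-authored polylines on a 512x512 canvas — the
downstream analysis only uses relative dissimilarities, so categorical and
configural structure matters, visual fidelity does not.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .strokes import Stroke, StrokeSet, arc_points, circle_points

__all__ = [
    "CATEGORIES",
    "CONDITIONS",
    "CANVAS_SIZE",
    "StimulusSpec",
    "UnknownStimulusError",
    "render_stimulus",
    "all_stimuli",
    "build_drawing_sets",
]

CATEGORIES = ("face", "house", "car", "human")
CONDITIONS = ("outline", "inner", "scrambled")
CANVAS_SIZE = 512


class UnknownStimulusError(ValueError):
    """Raised for a category or condition outside the experimental design."""


@dataclass(frozen=True)
class StimulusSpec:
    category: str
    condition: str
    part_templates: StrokeSet          # the strokes actually shown
    scramble_permutation: tuple        # permutation of inner-part positions

    @property
    def label(self) -> str:
        return f"{self.category}:{self.condition}"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise UnknownStimulusError(f"unknown category {self.category!r}")
        if self.condition not in CONDITIONS:
            raise UnknownStimulusError(f"unknown condition {self.condition!r}")


def _outline_strokes(category: str) -> StrokeSet:
    if category == "face":
        return StrokeSet((Stroke("face_outline", circle_points(256, 256, 190)),))
    if category == "house":
        roof = Stroke("roof", np.array([[106.0, 236.0], [256.0, 96.0], [406.0, 236.0]]))
        body = Stroke(
            "body",
            np.array(
                [[126.0, 236.0], [386.0, 236.0], [386.0, 436.0], [126.0, 436.0], [126.0, 236.0]]
            ),
        )
        return StrokeSet((roof, body))
    if category == "car":
        body = Stroke(
            "car_body",
            np.array(
                [
                    [96.0, 336.0],
                    [96.0, 296.0],
                    [176.0, 296.0],
                    [216.0, 246.0],
                    [336.0, 246.0],
                    [376.0, 296.0],
                    [416.0, 296.0],
                    [416.0, 336.0],
                    [96.0, 336.0],
                ]
            ),
        )
        return StrokeSet((body,))
    if category == "human":
        head = Stroke("head", circle_points(256, 116, 50))
        torso = Stroke("torso", np.array([[256.0, 166.0], [256.0, 316.0]]))
        arms = Stroke("arms", np.array([[186.0, 226.0], [326.0, 226.0]]))
        leg_l = Stroke("leg_left", np.array([[256.0, 316.0], [206.0, 426.0]]))
        leg_r = Stroke("leg_right", np.array([[256.0, 316.0], [306.0, 426.0]]))
        return StrokeSet((head, torso, arms, leg_l, leg_r))
    raise UnknownStimulusError(f"unknown category {category!r}")


def _inner_strokes(category: str) -> StrokeSet:
    if category == "face":
        return StrokeSet(
            (
                Stroke("left_eye", circle_points(196, 206, 22, n=20)),
                Stroke("right_eye", circle_points(316, 206, 22, n=20)),
                Stroke("nose", np.array([[256.0, 236.0], [244.0, 288.0], [268.0, 288.0]])),
                Stroke("mouth", arc_points(256, 296, 70, 30, 150)),
            )
        )
    if category == "house":
        door = Stroke(
            "door",
            np.array([[236.0, 436.0], [236.0, 336.0], [296.0, 336.0], [296.0, 436.0]]),
        )
        win_l = Stroke(
            "window_left",
            np.array(
                [[150.0, 270.0], [200.0, 270.0], [200.0, 320.0], [150.0, 320.0], [150.0, 270.0]]
            ),
        )
        win_r = Stroke(
            "window_right",
            np.array(
                [[312.0, 270.0], [362.0, 270.0], [362.0, 320.0], [312.0, 320.0], [312.0, 270.0]]
            ),
        )
        return StrokeSet((door, win_l, win_r))
    if category == "car":
        return StrokeSet(
            (
                Stroke("wheel_left", circle_points(176, 336, 36, n=24)),
                Stroke("wheel_right", circle_points(336, 336, 36, n=24)),
                Stroke(
                    "window",
                    np.array(
                        [[226.0, 256.0], [326.0, 256.0], [326.0, 296.0], [226.0, 296.0], [226.0, 256.0]]
                    ),
                ),
            )
        )
    if category == "human":
        return StrokeSet(
            (
                Stroke("left_eye", circle_points(238, 102, 9, n=12)),
                Stroke("right_eye", circle_points(274, 102, 9, n=12)),
                Stroke("mouth", arc_points(256, 122, 20, 40, 140, n=10)),
                Stroke("button_a", circle_points(256, 220, 10, n=12)),
                Stroke("button_b", circle_points(256, 262, 10, n=12)),
            )
        )
    raise UnknownStimulusError(f"unknown category {category!r}")


def _scramble_permutation(n_parts: int, rng: np.random.Generator) -> tuple:
    """A non-identity permutation of part positions (rejection-sampled)."""
    while True:
        perm = tuple(int(i) for i in rng.permutation(n_parts))
        if perm != tuple(range(n_parts)):
            return perm


def render_stimulus(category: str, condition: str, scramble_seed: int = 0) -> StimulusSpec:
    """Build the stimulus template for one (category, condition) cell.

    Deterministic per ``(category, condition, scramble_seed)``.  Outline
    stimuli carry only contour strokes; inner/scrambled stimuli carry only
    inner-part strokes, with positions permuted in the scrambled condition.
    """
    if category not in CATEGORIES:
        raise UnknownStimulusError(f"unknown category {category!r}")
    if condition not in CONDITIONS:
        raise UnknownStimulusError(f"unknown condition {condition!r}")

    if condition == "outline":
        return StimulusSpec(category, condition, _outline_strokes(category), ())

    inner = _inner_strokes(category)
    if condition == "inner":
        perm = tuple(range(len(inner)))
        return StimulusSpec(category, condition, inner, perm)

    # scrambled: move each part to another part's canonical centroid
    rng = np.random.default_rng(
        [scramble_seed, CATEGORIES.index(category), 7919]
    )
    perm = _scramble_permutation(len(inner), rng)
    anchors = [s.centroid for s in inner.strokes]
    moved = tuple(
        s.translated(anchors[perm[i]] - s.centroid) for i, s in enumerate(inner.strokes)
    )
    return StimulusSpec(category, condition, StrokeSet(moved), perm)


def complement_strokes(stimulus: StimulusSpec) -> StrokeSet:
    """The strokes a canonical completion adds: inner parts for an outline
    stimulus, the outline for an inner/scrambled stimulus."""
    if stimulus.condition == "outline":
        return _inner_strokes(stimulus.category)
    return _outline_strokes(stimulus.category)


def all_stimuli(scramble_seed: int = 0) -> list:
    """The full 12-stimulus design, in canonical (category, condition) order."""
    return [
        render_stimulus(cat, cond, scramble_seed)
        for cat, cond in itertools.product(CATEGORIES, CONDITIONS)
    ]


def build_drawing_sets(seed: int, scramble_seed: int = 0) -> list:
    """Partition two copies of each stimulus into 4 ordered sets of 6.

    Each set contains exactly two stimuli of each presentation condition and
    no category more than twice.  The partition is found by seeded rejection
    sampling, so it is deterministic per seed.
    """
    stimuli = all_stimuli(scramble_seed)
    by_label = {s.label: s for s in stimuli}
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        remaining = {s.label: 2 for s in stimuli}
        sets = []
        for _k in range(4):
            chosen = _draw_one_set(remaining, rng)
            if chosen is None:
                break
            for lbl in chosen:
                remaining[lbl] -= 1
            sets.append([by_label[lbl] for lbl in chosen])
        if len(sets) == 4:
            assert all(_valid_set(s) for s in sets)
            return sets
    raise RuntimeError("could not build drawing sets (should not happen)")


def _draw_one_set(remaining: dict, rng: np.random.Generator, tries: int = 200):
    """One set of 6 labels from the remaining pool: 2 per condition, no
    category more than twice, all labels distinct."""
    for _ in range(tries):
        chosen: list = []
        cat_count: dict = {}
        ok = True
        for cond in CONDITIONS:
            avail = [
                lbl
                for lbl, n in remaining.items()
                if n > 0
                and lbl.split(":")[1] == cond
                and lbl not in chosen
                and cat_count.get(lbl.split(":")[0], 0) < 2
            ]
            if len(avail) < 2:
                ok = False
                break
            picked = [avail[i] for i in rng.choice(len(avail), size=2, replace=False)]
            for lbl in picked:
                cat = lbl.split(":")[0]
                if cat_count.get(cat, 0) >= 2:
                    ok = False
                    break
                cat_count[cat] = cat_count.get(cat, 0) + 1
                chosen.append(lbl)
            if not ok:
                break
        if ok and len(chosen) == 6:
            return chosen
    return None


def _valid_set(stims: list) -> bool:
    conds = [s.condition for s in stims]
    cats = [s.category for s in stims]
    if any(conds.count(c) != 2 for c in CONDITIONS):
        return False
    if any(cats.count(c) > 2 for c in CATEGORIES):
        return False
    # no duplicate (category, condition) cell within a set
    labels = [s.label for s in stims]
    return len(set(labels)) == 6
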