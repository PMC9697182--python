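"""Synthetic cohort generator: child agents, simulated drawings, crowd raters, AQ sheets.

The generator is a stated world for the analysis pipeline, not a visual
model of children's art.  A :class:`ChildAgent` carries a style mixture over
{none, scribble, trace, color, complete, off_target} whose completion weight
rises and scribble weight falls with age (logistic trends), and an
*adaptation* probability ``alpha``: the probability that a stimulus-directed
style (complete / trace / color) is actually executed on the presented
stimulus rather than being replaced by the agent's fixed off-target motif.
``alpha`` is the generative ground truth that the per-child RDM score is
supposed to recover downstream.

Adults are pure completers (alpha = 1) with small motor jitter.  Raters score
seven statements on a 0-100 scale around style-conditional means and answer a
known-answer category question with configurable accuracy.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .strokes import Stroke, StrokeSet
from .stimuli import (
    CANVAS_SIZE,
    CATEGORIES,
    StimulusSpec,
    all_stimuli,
    build_drawing_sets,
    complement_strokes,
)

__all__ = [
    "STYLES",
    "CohortParams",
    "RaterParams",
    "ChildAgent",
    "RaterAgent",
    "Drawing",
    "CohortBundle",
    "sample_child",
    "simulate_drawing",
    "simulate_ratings",
    "simulate_cohort",
    "write_cohort",
]

STYLES = ("none", "scribble", "trace", "color", "complete", "off_target")

#: which rating statements (s1..s7) sit high for each drawn style
STATEMENT_STYLE = {
    "s1": "complete",
    "s2": "complete",
    "s3": "scribble",
    "s4": "scribble",
    "s5": "trace",
    "s6": "color",
}
RELATED_STYLES = frozenset({"complete", "trace", "color"})
GUESS_OPTIONS = CATEGORIES + ("dont_know",)


@dataclass(frozen=True)
class CohortParams:
    """Defaults encode the qualitative developmental trends the analysis assumes:
    scribbling falls and completion rises with age, and stimulus adaptation
    (alpha) increases with age."""

    age_min: int = 25
    age_max: int = 99
    age_mid: float = 48.0
    completion_slope: float = 0.12     # logistic slope (1/month) of the completion weight
    alpha_slope: float = 0.12          # logistic slope for mean alpha
    alpha_lo: float = 0.15
    alpha_hi: float = 0.97
    alpha_concentration: float = 12.0  # Beta concentration around the age-trend mean
    rest_weights: dict = field(
        default_factory=lambda: {
            "scribble": 0.40,
            "trace": 0.20,
            "color": 0.20,
            "off_target": 0.13,
            "none": 0.07,
        }
    )
    weight_concentration: float = 60.0  # Dirichlet concentration of per-child jitter
    aq_beta: tuple = (2.0, 4.0)         # item endorsement propensity prior
    aq_missingness: float = 0.02
    scramble_seed: int = 0
    n_adults: int = 5
    adult_repeats: int = 2
    adult_jitter_sd: float = 2.0


@dataclass(frozen=True)
class RaterParams:
    n_raters: int = 30
    raters_per_drawing: int = 5
    known_answer_accuracy: float = 0.85
    noise_sd: float = 8.0
    high_mean: float = 85.0
    low_mean: float = 10.0


@dataclass(frozen=True)
class ChildAgent:
    child_id: str
    age_months: int
    alpha: float
    style_weights: dict       # over STYLES, sums to 1
    motif_seed: int
    aq_propensity: float

    def __post_init__(self) -> None:
        w = np.array([self.style_weights[s] for s in STYLES])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("style_weights must be a probability vector over STYLES")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class RaterAgent:
    rater_id: str
    known_answer_accuracy: float
    noise_sd: float


@dataclass(frozen=True)
class Drawing:
    drawing_id: str
    child_id: str
    stimulus: StimulusSpec
    presented_strokes: StrokeSet
    produced_strokes: StrokeSet
    true_style: str

    @property
    def is_empty(self) -> bool:
        return len(self.produced_strokes) == 0


@dataclass
class CohortBundle:
    children: list
    drawings: list            # child drawings
    adult_drawings: list
    ratings: pd.DataFrame     # rater_id, drawing_id, s1..s7, guess
    aq_sheets: pd.DataFrame   # child_id, item_1..item_50 (NaN = missing)
    drawing_sets: list
    cohort_params: CohortParams
    rater_params: RaterParams
    seed: int

    @property
    def empty_drawing_ids(self) -> set:
        return {d.drawing_id for d in self.drawings if d.is_empty}

    @property
    def stimulus_truth(self) -> dict:
        """drawing_id -> true category, for rater QC."""
        return {d.drawing_id: d.stimulus.category for d in self.drawings}

    def drawings_by_child(self) -> dict:
        out: dict = {}
        for d in self.drawings:
            out.setdefault(d.child_id, []).append(d)
        return out

    def metadata(self) -> pd.DataFrame:
        by_id = {c.child_id: c for c in self.children}
        rows = []
        for d in self.drawings:
            agent = by_id[d.child_id]
            rows.append(
                dict(
                    drawing_id=d.drawing_id,
                    child_id=d.child_id,
                    age_months=agent.age_months,
                    category=d.stimulus.category,
                    condition=d.stimulus.condition,
                    true_style=d.true_style,
                    alpha=agent.alpha,
                )
            )
        return pd.DataFrame(rows)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def sample_child(
    age_months: int,
    params: CohortParams,
    rng: np.random.Generator,
    child_id: str = "c0",
) -> ChildAgent:
    """Draw one child agent whose style mixture and adaptation follow the
    cohort's age trends.

    The completion weight follows a logistic in age; the remaining mass is
    split among the other styles in fixed proportions (``rest_weights``), so
    scribbling — the largest share of the remainder — falls as completion
    rises.  A zero slope makes the mixture age-independent.  Per-child
    variability is a Dirichlet perturbation around the age-trend mean.
    """
    if not params.age_min <= age_months <= params.age_max:
        raise ValueError(
            f"age {age_months} months outside configured range "
            f"[{params.age_min}, {params.age_max}]"
        )
    rest = dict(params.rest_weights)
    total = sum(rest.values())
    if total <= 0:
        raise ValueError("rest_weights must have positive mass")
    rest = {k: v / total for k, v in rest.items()}
    p_complete = _sigmoid(params.completion_slope * (age_months - params.age_mid))
    mean_w = np.array(
        [
            (1.0 - p_complete) * rest["none"],
            (1.0 - p_complete) * rest["scribble"],
            (1.0 - p_complete) * rest["trace"],
            (1.0 - p_complete) * rest["color"],
            p_complete,
            (1.0 - p_complete) * rest["off_target"],
        ]
    )
    w = rng.dirichlet(params.weight_concentration * mean_w)
    # Dirichlet can return exact zeros for tiny concentrations; keep strictly valid
    w = np.clip(w, 0.0, None)
    w = w / w.sum()

    m = params.alpha_lo + (params.alpha_hi - params.alpha_lo) * _sigmoid(
        params.alpha_slope * (age_months - params.age_mid)
    )
    k = params.alpha_concentration
    alpha = float(rng.beta(m * k, (1.0 - m) * k))
    aq_propensity = float(rng.beta(*params.aq_beta))
    return ChildAgent(
        child_id=child_id,
        age_months=int(age_months),
        alpha=alpha,
        style_weights=dict(zip(STYLES, (float(v) for v in w))),
        motif_seed=int(rng.integers(0, 2**31 - 1)),
        aq_propensity=aq_propensity,
    )


def mean_alpha(age_months: float, params: CohortParams) -> float:
    """The configured mean of the alpha sampling distribution at one age."""
    return params.alpha_lo + (params.alpha_hi - params.alpha_lo) * _sigmoid(
        params.alpha_slope * (age_months - params.age_mid)
    )


def _motif_strokes(motif_seed: int) -> StrokeSet:
    """The agent's fixed off-target motif: a seed-determined star/zigzag placed
    at a seed-determined canvas quadrant.  Identical across stimuli."""
    rng = np.random.default_rng(motif_seed)
    quad = rng.integers(0, 4)
    cx = 150.0 + 212.0 * (quad % 2)
    cy = 150.0 + 212.0 * (quad // 2)
    n_arms = int(rng.integers(4, 8))
    r_out = float(rng.uniform(50, 90))
    r_in = r_out * 0.45
    t = np.linspace(0, 2 * np.pi, 2 * n_arms + 1) + float(rng.uniform(0, np.pi))
    radii = np.where(np.arange(2 * n_arms + 1) % 2 == 0, r_out, r_in)
    star = np.column_stack([cx + radii * np.cos(t), cy + radii * np.sin(t)])
    extra = np.column_stack(
        [
            cx + rng.uniform(-r_out, r_out, size=5),
            cy + rng.uniform(-r_out, r_out, size=5),
        ]
    )
    return StrokeSet((Stroke("motif_star", star), Stroke("motif_scrawl", extra)))


def _scribble_strokes(
    stimulus: StimulusSpec, alpha: float, rng: np.random.Generator
) -> StrokeSet:
    """5-30 short random polylines; each lands near the stimulus bounding box
    with probability alpha (so even scribbling can be stimulus-adaptive)."""
    n = int(rng.integers(5, 31))
    xmin, ymin, xmax, ymax = stimulus.part_templates.bounding_box()
    strokes = []
    for i in range(n):
        if rng.random() < alpha:
            cx = rng.uniform(xmin, xmax)
            cy = rng.uniform(ymin, ymax)
        else:
            cx = rng.uniform(0, CANVAS_SIZE)
            cy = rng.uniform(0, CANVAS_SIZE)
        n_pts = int(rng.integers(4, 9))
        steps = rng.normal(0.0, 18.0, size=(n_pts, 2))
        pts = np.clip(np.cumsum(steps, axis=0) + [cx, cy], 0, CANVAS_SIZE - 1)
        strokes.append(Stroke(f"scribble_{i}", pts))
    return StrokeSet(tuple(strokes))


def _color_strokes(stimulus: StimulusSpec) -> StrokeSet:
    """Colouring-in: dense horizontal hatching across the interior of the
    presented strokes' bounding box."""
    xmin, ymin, xmax, ymax = stimulus.part_templates.bounding_box()
    dx = (xmax - xmin) * 0.08
    dy = (ymax - ymin) * 0.08
    ys = np.arange(ymin + dy, ymax - dy, 7.0)
    strokes = [
        Stroke(f"hatch_{i}", np.array([[xmin + dx, y], [xmax - dx, y]]))
        for i, y in enumerate(ys)
    ]
    return StrokeSet(tuple(strokes))


def simulate_drawing(
    agent: ChildAgent, stimulus: StimulusSpec, rng: np.random.Generator, drawing_id: str = "d0"
) -> Drawing:
    """Sample one drawing from the agent's policy.

    With probability ``alpha`` the produced strokes are conditioned on the
    stimulus (complete = the complementary template, trace = a jittered copy
    of the presented strokes, color = hatching of the presented region,
    scribble = strokes biased toward the stimulus); with probability
    1 - alpha the agent draws its fixed motif regardless of the stimulus and
    the drawing is recorded as ``off_target`` (the label always describes
    what is on the canvas).  ``none`` leaves the canvas empty.
    """
    weights = np.array([agent.style_weights[s] for s in STYLES])
    style = STYLES[rng.choice(len(STYLES), p=weights / weights.sum())]

    if style == "none":
        produced: StrokeSet = StrokeSet(())
    elif style == "off_target":
        produced = _motif_strokes(agent.motif_seed)
    elif rng.random() >= agent.alpha:
        produced = _motif_strokes(agent.motif_seed)
        style = "off_target"
    elif style == "scribble":
        produced = _scribble_strokes(stimulus, agent.alpha, rng)
    elif style == "complete":
        produced = complement_strokes(stimulus)
    elif style == "trace":
        produced = stimulus.part_templates.jittered(rng, 4.0)
    else:  # color
        produced = _color_strokes(stimulus)

    return Drawing(
        drawing_id=drawing_id,
        child_id=agent.child_id,
        stimulus=stimulus,
        presented_strokes=stimulus.part_templates,
        produced_strokes=produced,
        true_style=style,
    )


def simulate_adult_drawing(
    adult_id: str, stimulus: StimulusSpec, rng: np.random.Generator,
    drawing_id: str, jitter_sd: float = 2.0,
) -> Drawing:
    """Adults always complete, with small motor jitter on the canonical strokes."""
    produced = complement_strokes(stimulus).jittered(rng, jitter_sd)
    return Drawing(
        drawing_id=drawing_id,
        child_id=adult_id,
        stimulus=stimulus,
        presented_strokes=stimulus.part_templates,
        produced_strokes=produced,
        true_style="complete",
    )


def simulate_ratings(
    drawing: Drawing,
    raters: list,
    rng: np.random.Generator,
    high_mean: float = 85.0,
    low_mean: float = 10.0,
) -> list:
    """One rating record per rater: seven statement scores (style-conditional
    mean + Gaussian noise, clipped to [0, 100]) and a known-answer category
    guess that is correct with the rater's accuracy."""
    if not raters:
        raise ValueError("simulate_ratings needs at least one rater")
    records = []
    for rater in raters:
        rec = {"rater_id": rater.rater_id, "drawing_id": drawing.drawing_id}
        for stmt, style in STATEMENT_STYLE.items():
            mu = high_mean if drawing.true_style == style else low_mean
            rec[stmt] = float(np.clip(mu + rng.normal(0.0, rater.noise_sd), 0.0, 100.0))
        mu7 = high_mean if drawing.true_style in RELATED_STYLES else low_mean
        rec["s7"] = float(np.clip(mu7 + rng.normal(0.0, rater.noise_sd), 0.0, 100.0))
        if rng.random() < rater.known_answer_accuracy:
            rec["guess"] = drawing.stimulus.category
        else:
            wrong = [g for g in GUESS_OPTIONS if g != drawing.stimulus.category]
            rec["guess"] = wrong[rng.integers(0, len(wrong))]
        records.append(rec)
    return records


def _simulate_aq_sheet(agent: ChildAgent, missingness: float, rng: np.random.Generator) -> dict:
    row: dict = {"child_id": agent.child_id}
    for i in range(1, 51):
        if rng.random() < missingness:
            row[f"item_{i}"] = np.nan
        else:
            row[f"item_{i}"] = float(rng.random() < agent.aq_propensity)
    return row


def simulate_cohort(
    n_children: int,
    cohort_params: CohortParams | None = None,
    rater_params: RaterParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> CohortBundle:
    """Simulate the full study: children (round-robin over 4 drawing sets of 6),
    adult reference drawings (every stimulus, ``adult_repeats`` times each),
    crowd ratings of all child drawings, and AQ answer sheets."""
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    cp = cohort_params or CohortParams()
    rp = rater_params or RaterParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)

    sets = build_drawing_sets(int(rng.integers(0, 2**31 - 1)), cp.scramble_seed)

    children = []
    drawings = []
    for i in range(n_children):
        age = int(rng.integers(cp.age_min, cp.age_max + 1))
        agent = sample_child(age, cp, rng, child_id=f"c{i:03d}")
        children.append(agent)
        for j, stim in enumerate(sets[i % 4]):
            drawings.append(
                simulate_drawing(agent, stim, rng, drawing_id=f"{agent.child_id}-d{j}")
            )

    adult_drawings = []
    for a in range(cp.n_adults):
        for s_idx, stim in enumerate(all_stimuli(cp.scramble_seed)):
            for r in range(cp.adult_repeats):
                adult_drawings.append(
                    simulate_adult_drawing(
                        f"adult{a}", stim, rng,
                        drawing_id=f"adult{a}-s{s_idx}-r{r}",
                        jitter_sd=cp.adult_jitter_sd,
                    )
                )

    raters = [
        RaterAgent(f"r{k:03d}", rp.known_answer_accuracy, rp.noise_sd)
        for k in range(rp.n_raters)
    ]
    records: list = []
    for d in drawings:
        chosen = rng.choice(rp.n_raters, size=min(rp.raters_per_drawing, rp.n_raters), replace=False)
        records.extend(
            simulate_ratings(d, [raters[k] for k in chosen], rng, rp.high_mean, rp.low_mean)
        )
    rating_df = pd.DataFrame(records)

    aq_df = pd.DataFrame([_simulate_aq_sheet(c, cp.aq_missingness, rng) for c in children])

    return CohortBundle(
        children=children,
        drawings=drawings,
        adult_drawings=adult_drawings,
        ratings=rating_df,
        aq_sheets=aq_df,
        drawing_sets=sets,
        cohort_params=cp,
        rater_params=rp,
        seed=seed,
    )


def write_cohort(bundle: CohortBundle, outdir, write_images: bool = True) -> None:
    """Serialize a cohort: metadata/ratings/AQ as CSV, drawings as PNG."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.metadata().to_csv(out / "metadata.csv", index=False)
    bundle.ratings.to_csv(out / "ratings.csv", index=False)
    bundle.aq_sheets.to_csv(out / "aq.csv", index=False)
    manifest = {
        "seed": bundle.seed,
        "n_children": len(bundle.children),
        "cohort_params": {k: v for k, v in asdict(bundle.cohort_params).items()},
        "rater_params": asdict(bundle.rater_params),
    }
    (out / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    if write_images:
        from .imageops import rasterize, save_png

        img_dir = out / "drawings"
        img_dir.mkdir(exist_ok=True)
        for d in bundle.drawings + bundle.adult_drawings:
            save_png(rasterize(d), img_dir / f"{d.drawing_id}.png")
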