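"""End-to-end orchestration: cohort -> ratings -> features -> RDMs -> statistics.

``run_pipeline`` runs every stage on a synthetic cohort and writes all
tables under one output directory, with a manifest recording the seed and a
hash of the configuration.  Everything downstream of the master seed is
deterministic, so two runs with the same config produce byte-identical CSVs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    assign_age_groups,
    compare_group_to_adult_rdm,
    correlate_rdm_completion,
    lrt_fixed_effect,
)
from .backbone import FeatureExtractor, load_pretrained_backbone, make_test_backbone
from .cohort import CohortParams, RaterParams, simulate_cohort, write_cohort
from .ratings import aggregate_drawing_scores, compute_aq, dominant_style, qc_filter_raters
from .rsa import RDM, child_rdm, group_rdm, rdm_score, select_style_sets, style_vs_adult_distances

logger = logging.getLogger(__name__)

_CSV_KW = dict(index=False, float_format="%.12g")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_children: int = 24
    backbone: str = "test"          # "test" or "vgg19"
    backbone_seed: int = 0
    layer: str = "fc7"              # layer for RDMs and the RDM score
    summary_layers: tuple = ("pool1", "fc6", "fc7")  # layers for style-vs-adult
    cutoff: float = 70.0
    qc_threshold: float = 0.7
    n_perm: int = 1000
    write_images: bool = True
    cohort_params: CohortParams = field(default_factory=CohortParams)
    rater_params: RaterParams = field(default_factory=RaterParams)


@dataclass
class PipelineResult:
    outdir: Path
    score_table: pd.DataFrame
    style_sets: dict
    group_rdms: dict
    adult_rdm: RDM
    child_scores: pd.DataFrame
    lrt_table: pd.DataFrame
    group_vs_adult: pd.DataFrame
    correlation: object


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _common_label_subset(rdms: dict) -> dict:
    """Restrict RDMs to the stimulus labels present in every matrix, so
    group-vs-adult comparisons are paired.  Warns only via log."""
    common = None
    for r in rdms.values():
        s = set(r.labels)
        common = s if common is None else common & s
    common_sorted = sorted(common)
    out = {}
    for key, r in rdms.items():
        if set(r.labels) == set(common_sorted) and list(r.labels) == common_sorted:
            out[key] = r
            continue
        idx = [r.labels.index(lbl) for lbl in common_sorted]
        out[key] = RDM(r.matrix[np.ix_(idx, idx)], tuple(common_sorted), r.layer, r.produced_only)
    if any(len(r.labels) != len(rdms[k].labels) for k, r in out.items()):
        logger.info("group RDMs restricted to %d common stimuli", len(common_sorted))
    return out


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- cohort -----------------------------------------------------------
    logger.info("stage: simulate cohort (n=%d)", config.n_children)
    bundle = simulate_cohort(
        config.n_children, config.cohort_params, config.rater_params,
        rng=np.random.default_rng(config.seed),
    )
    write_cohort(bundle, out / "cohort", write_images=config.write_images)
    metadata = bundle.metadata()

    # --- ratings ----------------------------------------------------------
    logger.info("stage: rating QC and aggregation")
    filtered = qc_filter_raters(bundle.ratings, bundle.stimulus_truth, config.qc_threshold)
    score_table = aggregate_drawing_scores(filtered, bundle.empty_drawing_ids)
    score_table.to_csv(out / "score_table.csv", **_CSV_KW)

    aq_rows = []
    for _, row in bundle.aq_sheets.iterrows():
        res = compute_aq(row[[f"item_{i}" for i in range(1, 51)]], child_id=row["child_id"])
        aq_rows.append(
            dict(child_id=res.child_id, n_answered=res.n_answered, raw_sum=res.raw_sum,
                 scaled_score=res.scaled_score, above_cutoff=res.above_cutoff)
        )
    aq_table = pd.DataFrame(aq_rows)
    aq_table.to_csv(out / "aq_scores.csv", **_CSV_KW)

    style_sets = select_style_sets(score_table, config.cutoff)
    pd.DataFrame(
        [
            {"style": s.style, "drawing_id": did, "cutoff": s.cutoff}
            for s in style_sets.values()
            for did in s.drawing_ids
        ],
        columns=["style", "drawing_id", "cutoff"],
    ).to_csv(out / "style_sets.csv", **_CSV_KW)

    # --- features ---------------------------------------------------------
    logger.info("stage: feature extraction (%s backbone)", config.backbone)
    if config.backbone == "test":
        net = make_test_backbone(config.backbone_seed)
    elif config.backbone == "vgg19":
        net = load_pretrained_backbone("vgg19-imagenet")
    else:
        raise ValueError(f"unknown backbone {config.backbone!r}")
    extractor = FeatureExtractor(net)

    # --- style-vs-adult distances (full drawings) -------------------------
    logger.info("stage: style-vs-adult distances")
    child_drawings = {d.drawing_id: d for d in bundle.drawings}
    summary_rows = []
    for layer in config.summary_layers:
        for style, sset in style_sets.items():
            if not len(sset):
                logger.info("style set %r empty at cutoff %s", style, config.cutoff)
                continue
            summ = style_vs_adult_distances(
                sset, child_drawings, bundle.adult_drawings, extractor, layer
            )
            summary_rows.append(
                dict(style=style, layer=layer, n=len(summ.per_drawing_distances),
                     mean=summ.mean, sd=summ.sd, n_skipped=len(summ.skipped))
            )
    pd.DataFrame(
        summary_rows, columns=["style", "layer", "n", "mean", "sd", "n_skipped"]
    ).to_csv(out / "distance_summary.csv", **_CSV_KW)

    # --- group RDMs (produced-only) ---------------------------------------
    logger.info("stage: group RDMs per age group")
    assignments = {a.child_id: a.group for a in assign_age_groups(bundle.children)}
    feats_by_group: dict = {g: {} for g in (1, 2, 3, 4)}
    for d in bundle.drawings:
        g = assignments[d.child_id]
        feats_by_group[g].setdefault(d.stimulus.label, []).append(
            extractor.features(d, config.layer, produced_only=True)
        )
    adult_feats: dict = {}
    for d in bundle.adult_drawings:
        adult_feats.setdefault(d.stimulus.label, []).append(
            extractor.features(d, config.layer, produced_only=True)
        )
    rdms = {f"group{g}": group_rdm({k: v for k, v in sorted(f.items())}, config.layer)
            for g, f in feats_by_group.items() if f}
    rdms["adult"] = group_rdm({k: v for k, v in sorted(adult_feats.items())}, config.layer)
    rdms = _common_label_subset(rdms)
    for name, r in rdms.items():
        r.validate()
        r.to_csv(out / f"rdm_{name}.csv")

    logger.info("stage: group-vs-adult permutation tests")
    perm_rng = np.random.default_rng([config.seed, 2])
    cmp_rows = []
    for g in (1, 2, 3, 4):
        key = f"group{g}"
        if key not in rdms:
            continue
        p = compare_group_to_adult_rdm(rdms[key], rdms["adult"], config.n_perm, perm_rng)
        # no correction across the four group tests; flagged in the output
        cmp_rows.append(dict(group=g, p=p, n_perm=config.n_perm, mc_correction="none"))
    group_vs_adult = pd.DataFrame(cmp_rows, columns=["group", "p", "n_perm", "mc_correction"])
    group_vs_adult.to_csv(out / "group_vs_adult.csv", **_CSV_KW)

    # --- per-child RDMs and scores ----------------------------------------
    logger.info("stage: per-child RDM scores")
    child_rows = []
    by_child = bundle.drawings_by_child()
    age_of = {c.child_id: c.age_months for c in bundle.children}
    alpha_of = {c.child_id: c.alpha for c in bundle.children}
    for child_id in sorted(by_child):
        try:
            r = child_rdm(by_child[child_id], extractor, config.layer)
        except ValueError as exc:
            logger.info("child %s excluded from RDM analysis: %s", child_id, exc)
            continue
        r.validate()
        ids = [d.drawing_id for d in by_child[child_id]]
        comp = score_table[score_table["drawing_id"].isin(ids)]["completion"].mean()
        child_rows.append(
            dict(child_id=child_id, age_months=age_of[child_id], alpha=alpha_of[child_id],
                 rdm_score=rdm_score(r), completion_score=float(comp),
                 dominant_style=dominant_style(score_table, ids))
        )
    child_scores = pd.DataFrame(child_rows)
    child_scores.to_csv(out / "child_rdm_scores.csv", **_CSV_KW)

    # --- mixed-model LRTs --------------------------------------------------
    logger.info("stage: mixed-model likelihood-ratio tests")
    rows = metadata.merge(score_table, on="drawing_id")
    aq_map = aq_table.set_index("child_id")["scaled_score"]
    rows["aq"] = rows["child_id"].map(aq_map)
    lrt_rows = []
    for response in ("completion", "scribbling"):
        res = lrt_fixed_effect(
            rows, response, ["age_months"], "age_months",
            ["child_id", "category", "condition"],
        )
        lrt_rows.append(dict(response=response, term="age_months",
                             chi2=res.chi2, df=res.df, p=res.p))
        sub = rows.dropna(subset=["aq"])
        res = lrt_fixed_effect(
            sub, response, ["age_months", "aq"], "aq",
            ["child_id", "category", "condition"],
        )
        lrt_rows.append(dict(response=response, term="aq", chi2=res.chi2, df=res.df, p=res.p))
    lrt_table = pd.DataFrame(lrt_rows, columns=["response", "term", "chi2", "df", "p"])
    lrt_table.to_csv(out / "lrt.csv", **_CSV_KW)

    # --- RDM score vs completion score ------------------------------------
    corr = correlate_rdm_completion(
        child_scores["rdm_score"].to_numpy(), child_scores["completion_score"].to_numpy()
    )
    pd.DataFrame(
        [dict(r=corr.r, df=corr.df, p=corr.p)], columns=["r", "df", "p"]
    ).to_csv(out / "correlation.csv", **_CSV_KW)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": asdict(config),
        "n_children": config.n_children,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    return PipelineResult(
        outdir=out,
        score_table=score_table,
        style_sets=style_sets,
        group_rdms={k: v for k, v in rdms.items() if k != "adult"},
        adult_rdm=rdms["adult"],
        child_scores=child_scores,
        lrt_table=lrt_table,
        group_vs_adult=group_vs_adult,
        correlation=corr,
    )
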