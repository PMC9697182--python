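"""Shared fixtures: one session-scoped demonstration cohort and feature cache.

The demonstration cohort (100 children, master seed 7) is the desk-scale
stand-in for a museum cohort; several statistical tests reuse it, so it is
built once per session.
"""
import numpy as np
import pandas as pd
import pytest

from drawrsa import FeatureExtractor, make_test_backbone, simulate_cohort
from drawrsa.ratings import aggregate_drawing_scores, qc_filter_raters
from drawrsa.rsa import child_rdm, group_rdm, rdm_score
from drawrsa.analysis import assign_age_groups
from drawrsa.pipeline import _common_label_subset

DEMO_SEED = 7
DEMO_N_CHILDREN = 100


@pytest.fixture(scope="session")
def test_net():
    return make_test_backbone(0)


@pytest.fixture(scope="session")
def extractor(test_net):
    return FeatureExtractor(test_net)


@pytest.fixture(scope="session")
def demo_bundle():
    return simulate_cohort(DEMO_N_CHILDREN, rng=np.random.default_rng(DEMO_SEED))


@pytest.fixture(scope="session")
def demo_score_table(demo_bundle):
    filtered = qc_filter_raters(demo_bundle.ratings, demo_bundle.stimulus_truth)
    return aggregate_drawing_scores(filtered, demo_bundle.empty_drawing_ids)


@pytest.fixture(scope="session")
def demo_child_rdms(demo_bundle, extractor):
    by_child = demo_bundle.drawings_by_child()
    return {cid: child_rdm(drawings, extractor) for cid, drawings in sorted(by_child.items())}


@pytest.fixture(scope="session")
def demo_child_table(demo_bundle, demo_child_rdms, demo_score_table):
    by_child = demo_bundle.drawings_by_child()
    rows = []
    for agent in demo_bundle.children:
        ids = [d.drawing_id for d in by_child[agent.child_id]]
        comp = demo_score_table[demo_score_table["drawing_id"].isin(ids)]["completion"].mean()
        rows.append(
            dict(
                child_id=agent.child_id,
                age_months=agent.age_months,
                alpha=agent.alpha,
                rdm_score=rdm_score(demo_child_rdms[agent.child_id]),
                completion_score=float(comp),
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def demo_group_rdms(demo_bundle, extractor):
    """Age-group and adult stimulus RDMs, restricted to common labels."""
    groups = {a.child_id: a.group for a in assign_age_groups(demo_bundle.children)}
    feats = {g: {} for g in (1, 2, 3, 4)}
    for d in demo_bundle.drawings:
        feats[groups[d.child_id]].setdefault(d.stimulus.label, []).append(
            extractor.features(d, "fc7", produced_only=True)
        )
    adult = {}
    for d in demo_bundle.adult_drawings:
        adult.setdefault(d.stimulus.label, []).append(
            extractor.features(d, "fc7", produced_only=True)
        )
    rdms = {g: group_rdm(dict(sorted(f.items()))) for g, f in feats.items() if f}
    rdms["adult"] = group_rdm(dict(sorted(adult.items())))
    return _common_label_subset(rdms)
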