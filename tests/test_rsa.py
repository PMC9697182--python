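"""Pearson-distance RSA: distance identities, RDM construction, style sets."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from drawrsa.backbone import FeatureVector
from drawrsa.cohort import CohortParams, RaterParams, simulate_cohort, simulate_drawing
from drawrsa.ratings import aggregate_drawing_scores, qc_filter_raters
from drawrsa.rsa import (
    RDM,
    MissingLabelError,
    ZeroVarianceWarning,
    block_contrast,
    child_rdm,
    group_rdm,
    pearson_distance,
    rdm_score,
    select_style_sets,
    style_vs_adult_distances,
)
from drawrsa.stimuli import render_stimulus
from .test_cohort import _delta_agent

finite_vec = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=3, max_size=30
)


class TestPearsonDistance:
    def test_small_vector_oracle(self):
        # frozen from 1 - Pearson r of (1,2,3) vs (1,2,4)
        assert pearson_distance([1, 2, 3], [1, 2, 4]) == pytest.approx(0.01801949, abs=1e-7)

    def test_identity_and_antipodal_are_exact(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        assert pearson_distance(x, x) == 0.0
        assert pearson_distance(x, -x) == 2.0

    @settings(derandomize=True, max_examples=100)
    @given(finite_vec)
    def test_symmetry_and_range(self, xs):
        rng = np.random.default_rng(7)
        x = np.asarray(xs)
        y = rng.standard_normal(x.size)
        if np.all(x == x[0]):
            return
        d = pearson_distance(x, y)
        assert 0.0 <= d <= 2.0
        assert d == pearson_distance(y, x)

    @settings(derandomize=True, max_examples=100)
    @given(finite_vec, st.floats(min_value=0.01, max_value=100), st.floats(-1e3, 1e3))
    def test_affine_invariance(self, xs, a, b):
        x = np.asarray(xs)
        if np.all(x == x[0]):
            return
        rng = np.random.default_rng(11)
        y = rng.standard_normal(x.size)
        assert pearson_distance(a * x + b, y) == pytest.approx(
            pearson_distance(x, y), abs=1e-9
        )

    def test_negation_complement(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        assert pearson_distance(-x, y) == pytest.approx(2.0 - pearson_distance(x, y), abs=1e-12)

    def test_constant_vector_conventions(self):
        with pytest.warns(ZeroVarianceWarning):
            assert pearson_distance([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]) == 0.0
        with pytest.warns(ZeroVarianceWarning):
            assert pearson_distance([3.0, 3.0, 3.0], [4.0, 4.0, 4.0]) == 2.0
        with pytest.warns(ZeroVarianceWarning):
            assert pearson_distance([3.0, 3.0, 3.0], [1.0, 2.0, 5.0]) == 2.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="length"):
            pearson_distance([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="layer"):
            pearson_distance(
                FeatureVector("fc6", [1.0, 2.0, 3.0]), FeatureVector("fc7", [1.0, 2.0, 4.0])
            )


class TestGroupRDM:
    def test_identical_vectors_give_zero_matrix(self):
        v = np.array([1.0, 2.0, 5.0])
        rdm = group_rdm({"a": [v], "b": [v.copy()], "c": [v.copy()]})
        assert np.allclose(rdm.matrix, 0.0)

    def test_two_labels_symmetric(self):
        rdm = group_rdm({"a": [[1.0, 2.0, 3.0]], "b": [[2.0, 1.0, 5.0]]})
        assert rdm.matrix[0, 1] == rdm.matrix[1, 0] > 0

    def test_average_then_distance_matches_numpy_oracle(self):
        rng = np.random.default_rng(2)
        feats = {lbl: [rng.standard_normal(6) for _ in range(2)] for lbl in "abc"}
        rdm = group_rdm(feats)
        means = {lbl: np.mean(v, axis=0) for lbl, v in feats.items()}
        for i, li in enumerate("abc"):
            for j, lj in enumerate("abc"):
                if i == j:
                    continue
                expected = 1.0 - np.corrcoef(means[li], means[lj])[0, 1]
                assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_missing_label_named_in_error(self):
        with pytest.raises(MissingLabelError, match="house:inner"):
            group_rdm({"face:outline": [[1.0, 2.0, 3.0]], "house:inner": []})


class TestChildRDM:
    def test_incomplete_set_rejected(self, extractor):
        bundle = simulate_cohort(1, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="complete set"):
            child_rdm(bundle.drawings[:4], extractor)

    def test_repetitive_child_has_near_zero_rdm(self, extractor):
        """A pure motif-repeater draws the same image on all 6 stimuli, so all
        off-diagonal entries vanish."""
        bundle = simulate_cohort(1, rng=np.random.default_rng(0))
        stims = [d.stimulus for d in bundle.drawings[:6]]
        agent = _delta_agent("complete", alpha=0.0, motif_seed=5, child_id="rep")
        rng = np.random.default_rng(1)
        drawings = [
            simulate_drawing(agent, s, rng, drawing_id=f"rep-{i}") for i, s in enumerate(stims)
        ]
        rdm = child_rdm(drawings, extractor)
        rdm.validate()
        assert rdm_score(rdm) == pytest.approx(0.0, abs=1e-9)

    def test_adaptive_exceeds_repetitive_rdm_score(self, extractor):
        """Seed-paired agents: the alpha = 1 completer always outscores the
        alpha = 0 motif-repeater (12 pairs, scaled-down Monte-Carlo)."""
        bundle = simulate_cohort(1, rng=np.random.default_rng(0))
        stims = [d.stimulus for d in bundle.drawings[:6]]
        diffs = []
        for k in range(12):
            rng = np.random.default_rng(100 + k)
            completer = _delta_agent("complete", 1.0, motif_seed=k, child_id=f"a{k}")
            repeater = _delta_agent("complete", 0.0, motif_seed=k, child_id=f"r{k}")
            dc = [simulate_drawing(completer, s, rng, f"a{k}-{i}") for i, s in enumerate(stims)]
            dr = [simulate_drawing(repeater, s, rng, f"r{k}-{i}") for i, s in enumerate(stims)]
            diffs.append(
                rdm_score(child_rdm(dc, extractor)) - rdm_score(child_rdm(dr, extractor))
            )
        assert np.mean(diffs) > 0
        assert np.min(diffs) > 0


class TestRDMScore:
    def test_two_by_two(self):
        assert rdm_score(RDM([[0, 0.3], [0.3, 0]], ("a", "b"))) == pytest.approx(0.3)

    def test_all_zero(self):
        assert rdm_score(RDM(np.zeros((3, 3)), ("a", "b", "c"))) == 0.0

    def test_three_by_three_mean(self):
        m = np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
        assert rdm_score(RDM(m, ("a", "b", "c"))) == pytest.approx(0.4)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            rdm_score(RDM(np.zeros((1, 1)), ("a",)))


class TestStyleSets:
    def test_strict_cutoff(self):
        table = pd.DataFrame(
            dict(drawing_id=["d0", "d1"], completion=[70.0, 70.1],
                 scribbling=[0.0, 0.0], tracing=[0.0, 0.0], coloring=[0.0, 0.0])
        )
        sets = select_style_sets(table, cutoff=70.0)
        assert sets["completion"].drawing_ids == ("d1",)

    def test_zero_cutoff_includes_positive_scores(self):
        table = pd.DataFrame(
            dict(drawing_id=["d0", "d1"], completion=[5.0, 0.0],
                 scribbling=[1.0, 0.0], tracing=[0.0, 0.0], coloring=[0.0, 2.0])
        )
        sets = select_style_sets(table, cutoff=0.0)
        assert sets["completion"].drawing_ids == ("d0",)
        assert sets["coloring"].drawing_ids == ("d1",)
        assert sets["tracing"].drawing_ids == ()

    def test_noiseless_ratings_recover_ground_truth_partitions(self):
        """With perfect raters, style sets at cutoff 70 equal the ground-truth
        style partitions of the simulated drawings."""
        bundle = simulate_cohort(
            30,
            rater_params=RaterParams(noise_sd=0.0, known_answer_accuracy=1.0),
            rng=np.random.default_rng(4),
        )
        filtered = qc_filter_raters(bundle.ratings, bundle.stimulus_truth)
        table = aggregate_drawing_scores(filtered, bundle.empty_drawing_ids)
        sets = select_style_sets(table, cutoff=70.0)
        truth = {"completion": "complete", "scribbling": "scribble",
                 "tracing": "trace", "coloring": "color"}
        for rated, true in truth.items():
            expected = {d.drawing_id for d in bundle.drawings if d.true_style == true}
            assert set(sets[rated].drawing_ids) == expected


class TestStyleVsAdult:
    def test_identical_child_and_adult_sets_give_zero_mean(self, extractor):
        bundle = simulate_cohort(1, rng=np.random.default_rng(0))
        stim = bundle.drawings[0].stimulus
        agent = _delta_agent("complete", 1.0)
        child = simulate_drawing(agent, stim, np.random.default_rng(1), drawing_id="kid")
        adult = simulate_drawing(agent, stim, np.random.default_rng(2), drawing_id="grown")
        from drawrsa.rsa import StyleSet

        summary = style_vs_adult_distances(
            StyleSet("completion", ("kid",), 70.0), {"kid": child}, [adult], extractor, "fc7"
        )
        # both drew the canonical completion, so the full drawings coincide
        assert summary.mean == pytest.approx(0.0, abs=1e-9)

    def test_unmatched_stimulus_skipped(self, extractor):
        bundle = simulate_cohort(1, rng=np.random.default_rng(0))
        d0, d1 = bundle.drawings[0], bundle.drawings[1]
        agent = _delta_agent("complete", 1.0)
        adult = simulate_drawing(agent, d0.stimulus, np.random.default_rng(2), drawing_id="ad")
        from drawrsa.rsa import StyleSet

        summary = style_vs_adult_distances(
            StyleSet("completion", (d0.drawing_id, d1.drawing_id), 70.0),
            {d0.drawing_id: d0, d1.drawing_id: d1},
            [adult],
            extractor,
            "fc7",
        )
        assert summary.skipped == (d1.drawing_id,)
        assert len(summary.per_drawing_distances) == 1


class TestBlockContrast:
    def _rdm(self, within, between):
        # labels: a1 a2 b1 b2; categories a, b
        m = np.full((4, 4), between)
        m[0, 1] = m[1, 0] = m[2, 3] = m[3, 2] = within
        np.fill_diagonal(m, 0.0)
        return RDM(m, ("a1", "a2", "b1", "b2"))

    def test_arithmetic(self):
        rdm = self._rdm(0.1, 0.5)
        assert block_contrast(rdm, lambda lbl: lbl[0]) == pytest.approx(0.4)

    def test_label_permutation_null_is_centred_on_zero(self):
        """Shuffling category assignments destroys the block structure, so the
        permutation-average contrast is ~0 (Monte-Carlo, 500 shuffles)."""
        rng = np.random.default_rng(3)
        n = 8
        m = np.abs(rng.standard_normal((n, n)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = tuple(f"s{i}" for i in range(n))
        rdm = RDM(m, labels)
        cats = np.array(["a"] * 4 + ["b"] * 4)
        vals = []
        for _ in range(500):
            perm = rng.permutation(n)
            mapping = dict(zip(labels, cats[perm]))
            vals.append(block_contrast(rdm, mapping))
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals)) + 1e-3

    def test_single_category_rejected(self):
        rdm = self._rdm(0.1, 0.5)
        with pytest.raises(ValueError):
            block_contrast(rdm, lambda lbl: "same")

    def test_contrast_increases_with_cohort_adaptation(self, extractor):
        """Group-level block structure strengthens as the cohort's mean
        adaptation rises (alpha-controlled cohorts, 24 children each,
        scaled-down from the nominal 100)."""
        contrasts = []
        for lo_hi in ((0.02, 0.05), (0.45, 0.55), (0.95, 0.99)):
            params = CohortParams(alpha_lo=lo_hi[0], alpha_hi=lo_hi[1])
            bundle = simulate_cohort(24, cohort_params=params,
                                     rng=np.random.default_rng(21))
            feats = {}
            for d in bundle.drawings:
                feats.setdefault(d.stimulus.label, []).append(
                    extractor.features(d, "fc7", produced_only=True)
                )
            rdm = group_rdm(dict(sorted(feats.items())))
            contrasts.append(block_contrast(rdm, lambda lbl: lbl.split(":")[0]))
        assert contrasts[0] < contrasts[1] < contrasts[2]


def test_rdm_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    m = np.abs(rng.standard_normal((3, 3)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    rdm = RDM(m, ("x", "y", "z"), layer="fc6", produced_only=False)
    rdm.to_csv(tmp_path / "rdm.csv")
    back = RDM.from_csv(tmp_path / "rdm.csv")
    assert back.labels == rdm.labels and back.layer == "fc6" and back.produced_only is False
    assert np.allclose(back.matrix, rdm.matrix)
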