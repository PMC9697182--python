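"""Rating aggregation, rater QC, AQ scoring, and dominant-style labelling."""
import numpy as np
import pandas as pd
import pytest

from drawrsa.cohort import RaterParams, simulate_cohort
from drawrsa.ratings import (
    aggregate_drawing_scores,
    compute_aq,
    dominant_style,
    qc_filter_raters,
    rater_accuracies,
)


def _records(rows):
    defaults = {s: 0.0 for s in ("s1", "s2", "s3", "s4", "s5", "s6", "s7")}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestRaterQC:
    TRUTH = {f"d{i}": "face" for i in range(10)}

    def _rater(self, rater_id, n_correct):
        rows = []
        for i in range(10):
            rows.append(
                dict(rater_id=rater_id, drawing_id=f"d{i}",
                     guess="face" if i < n_correct else "car")
            )
        return rows

    def test_perfect_rater_retained(self):
        recs = _records(self._rater("good", 10))
        out = qc_filter_raters(recs, self.TRUTH)
        assert set(out["rater_id"]) == {"good"}

    def test_exactly_seventy_percent_removed(self):
        """'More than 70%' is strict: accuracy 0.70 fails QC."""
        recs = _records(self._rater("borderline", 7) + self._rater("above", 8))
        acc = rater_accuracies(recs, self.TRUTH)
        assert acc["borderline"] == pytest.approx(0.7)
        out = qc_filter_raters(recs, self.TRUTH)
        assert set(out["rater_id"]) == {"above"}

    def test_low_accuracy_raters_removed_more_often(self):
        """Monte-Carlo over 200 raters: q = 0.5 raters fail QC far more often
        than q = 0.9 raters."""
        rng = np.random.default_rng(0)
        rows = []
        for k in range(200):
            q = 0.5 if k % 2 == 0 else 0.9
            for i in range(10):
                guess = "face" if rng.random() < q else "car"
                rows.append(dict(rater_id=f"r{k:03d}", drawing_id=f"d{i}", guess=guess))
        recs = _records(rows)
        surviving = set(qc_filter_raters(recs, self.TRUTH)["rater_id"])
        removed_low = np.mean([f"r{k:03d}" not in surviving for k in range(0, 200, 2)])
        removed_high = np.mean([f"r{k:03d}" not in surviving for k in range(1, 200, 2)])
        assert removed_low > removed_high

    def test_qc_threshold_monotonicity(self):
        recs = _records(self._rater("a", 6) + self._rater("b", 8) + self._rater("c", 10))
        counts = [
            len(qc_filter_raters(recs, self.TRUTH, threshold=t)) for t in (0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAggregation:
    def test_single_rater_completion_average(self):
        recs = _records([dict(rater_id="r0", drawing_id="d0", s1=80.0, s2=60.0, guess="face")])
        table = aggregate_drawing_scores(recs)
        assert table.loc[0, "completion"] == pytest.approx(70.0)

    def test_two_rater_mean(self):
        recs = _records(
            [
                dict(rater_id="r0", drawing_id="d0", s1=40.0, s2=40.0, guess="face"),
                dict(rater_id="r1", drawing_id="d0", s1=60.0, s2=60.0, guess="face"),
            ]
        )
        table = aggregate_drawing_scores(recs)
        assert table.loc[0, "completion"] == pytest.approx(50.0)

    def test_empty_drawing_overrides_ratings_with_zero(self):
        recs = _records([dict(rater_id="r0", drawing_id="d0", s1=90.0, s2=90.0, guess="face")])
        table = aggregate_drawing_scores(recs, empty_drawings={"d0"})
        row = table.set_index("drawing_id").loc["d0"]
        for col in ("completion", "scribbling", "tracing", "coloring", "relatedness"):
            assert row[col] == 0.0
        assert row["n_raters_used"] == 0

    def test_rater_order_invariance(self):
        rng = np.random.default_rng(1)
        rows = [
            dict(rater_id=f"r{k}", drawing_id=f"d{i}",
                 **{s: float(rng.uniform(0, 100)) for s in ("s1", "s2", "s3", "s4", "s5", "s6", "s7")},
                 guess="face")
            for k in range(4)
            for i in range(3)
        ]
        recs = _records(rows)
        shuffled = recs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            aggregate_drawing_scores(recs), aggregate_drawing_scores(shuffled)
        )

    def test_scores_stay_in_range(self):
        bundle = simulate_cohort(10, rater_params=RaterParams(noise_sd=40.0),
                                 rng=np.random.default_rng(2))
        table = aggregate_drawing_scores(bundle.ratings, bundle.empty_drawing_ids)
        for col in ("completion", "scribbling", "tracing", "coloring", "relatedness"):
            assert table[col].between(0, 100).all()


class TestAQ:
    def _sheet(self, n_answered, n_positive):
        vals = [1.0] * n_positive + [0.0] * (n_answered - n_positive)
        vals += [np.nan] * (50 - n_answered)
        return vals

    def test_fully_answered_identity(self):
        res = compute_aq(self._sheet(50, 18))
        assert res.n_answered == 50 and res.scaled_score == pytest.approx(18.0)

    def test_scaling_at_forty_answered(self):
        res = compute_aq(self._sheet(40, 20))
        assert res.scaled_score == pytest.approx(25.0)

    def test_below_threshold_missing(self):
        res = compute_aq(self._sheet(39, 20))
        assert res.scaled_score is None and res.above_cutoff is None

    def test_malformed_items_rejected(self):
        sheet = self._sheet(50, 10)
        sheet[0] = 2.0
        with pytest.raises(ValueError, match="0/1/missing"):
            compute_aq(sheet)

    def test_cutoff_flag_reported_not_filtering(self):
        res = compute_aq(self._sheet(50, 35))
        assert res.scaled_score == 35.0 and res.above_cutoff is True

    @pytest.mark.parametrize("n_answered,raw", [(50, 0), (50, 50), (45, 9), (41, 41)])
    def test_scaling_rule(self, n_answered, raw):
        res = compute_aq(self._sheet(n_answered, raw))
        assert res.scaled_score == pytest.approx(raw * 50 / n_answered)


class TestDominantStyle:
    TABLE = pd.DataFrame(
        dict(
            drawing_id=["d0", "d1"],
            completion=[80.0, 90.0],
            scribbling=[0.0, 0.0],
            tracing=[10.0, 10.0],
            coloring=[0.0, 0.0],
        )
    )

    def test_clear_winner(self):
        assert dominant_style(self.TABLE, ["d0", "d1"]) == "completion"

    def test_tie_breaks_toward_completion(self):
        table = self.TABLE.copy()
        table["scribbling"] = table["completion"]
        assert dominant_style(table, ["d0", "d1"]) == "completion"

    def test_no_scored_drawings_gives_none(self):
        assert dominant_style(self.TABLE, ["missing"]) is None

    def test_noiseless_cohort_recovers_modal_true_style(self):
        """With perfect raters, the dominant rated style equals the child's
        modal simulated style for >= 95% of children whose modal style is one
        of the four rated styles (n = 100)."""
        bundle = simulate_cohort(
            100,
            rater_params=RaterParams(noise_sd=0.0, known_answer_accuracy=1.0),
            rng=np.random.default_rng(8),
        )
        table = aggregate_drawing_scores(bundle.ratings, bundle.empty_drawing_ids)
        to_rated = {"complete": "completion", "scribble": "scribbling",
                    "trace": "tracing", "color": "coloring"}
        order = ("complete", "scribble", "trace", "color")
        hits, total = 0, 0
        for child_id, drawings in bundle.drawings_by_child().items():
            styles = [d.true_style for d in drawings]
            counts = {s: styles.count(s) for s in order}
            if max(counts.values()) == 0:
                continue
            modal = max(order, key=lambda s: counts[s])
            total += 1
            ids = [d.drawing_id for d in drawings]
            hits += dominant_style(table, ids) == to_rated[modal]
        assert total > 50
        assert hits / total >= 0.95
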