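"""Pooled AUC-ROC, harmonic mean, aggregation, and the sweep harness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gfchest as g
from gfchest.evaluation import report_to_markdown


def mann_whitney_auc(y, s):
    """Exhaustive pair-counting oracle: concordant + half of tied pairs."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return 100.0 * (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestPooledAuc:
    def test_perfect_ranking_is_100(self):
        labels = np.array([[1, 0], [0, 1], [0, 0]])
        probs = np.where(labels == 1, 0.9, 0.1)
        assert g.pooled_auc(labels, probs) == 100.0

    def test_all_ties_is_50(self):
        labels = np.array([[1, 0], [0, 1]])
        probs = np.full((2, 2), 0.4)
        assert g.pooled_auc(labels, probs) == 50.0

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            labels = rng.integers(0, 2, size=(8, 3))
            if labels.min() == labels.max():
                continue
            # Quantized scores force ties through the midrank path.
            probs = rng.integers(0, 5, size=(8, 3)) / 4.0
            expected = mann_whitney_auc(labels.ravel(), probs.ravel())
            assert g.pooled_auc(labels, probs) == pytest.approx(expected)

    def test_class_subset_selection(self):
        labels = np.array([[1, 0, 1], [0, 0, 0], [1, 1, 0]])
        probs = np.array([[0.9, 0.2, 0.8], [0.1, 0.3, 0.2], [0.8, 0.7, 0.1]])
        full = g.pooled_auc(labels, probs, [0, 2])
        manual = mann_whitney_auc(labels[:, [0, 2]].ravel(), probs[:, [0, 2]].ravel())
        assert full == pytest.approx(manual)

    def test_single_class_labels_undefined(self):
        with pytest.raises(g.UndefinedMetricError):
            g.pooled_auc(np.ones((3, 2)), np.random.rand(3, 2))

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.floats(0.01, 0.99)),
                 min_size=4, max_size=30)
    )
    def test_invariance_under_monotone_transforms(self, pairs):
        y = np.array([p[0] for p in pairs])[:, None]
        s = np.array([p[1] for p in pairs])[:, None]
        if y.min() == y.max():
            return
        base = g.pooled_auc(y, s)
        assert g.pooled_auc(y, np.exp(3 * s)) == pytest.approx(base)
        assert g.pooled_auc(y, 0.1 + 0.5 * s) == pytest.approx(base)


class TestHarmonicMean:
    @given(st.floats(0.0, 100.0))
    def test_idempotent(self, a):
        assert g.harmonic_mean(a, a) == pytest.approx(a)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    def test_symmetric_and_bounded_by_arithmetic_mean(self, a, b):
        hm = g.harmonic_mean(a, b)
        assert hm == pytest.approx(g.harmonic_mean(b, a))
        assert hm <= (a + b) / 2 + 1e-9
        if abs(a - b) > 1e-6:
            assert hm < (a + b) / 2

    def test_zero_absorbing(self):
        assert g.harmonic_mean(60.0, 0.0) == 0.0

    def test_closed_form(self):
        assert g.harmonic_mean(100.0, 50.0) == pytest.approx(200.0 / 3.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            g.harmonic_mean(-1.0, 50.0)


class TestScoreEpisode:
    def make_episode_and_table(self):
        from conftest import SMALL_VOCAB, make_record

        records = [
            make_record(0, ["Alpha"]),
            make_record(1, ["Gamma"]),
            make_record(2, []),
            make_record(3, ["Alpha", "Gamma"]),
        ]
        table = g.MetadataTable.from_records(records, SMALL_VOCAB)
        episode = g.Episode(
            seen_classes=("Alpha",),
            unseen_classes=("Gamma",),
            excluded_classes=frozenset({"Beta", "Delta"}),
            trn_ids=("r000",),
            tst_ids=("r000", "r001", "r002", "r003"),
            pool="tst",
        )
        return episode, table

    def test_perfect_predictions_score_100(self):
        episode, table = self.make_episode_and_table()
        labels = episode.label_matrix(table, "tst").astype(float)
        pred = g.PredictionMatrix(
            probs=labels * 0.8 + 0.1, classes=episode.classes,
            record_ids=episode.tst_ids,
        )
        scores = g.score_episode(episode, pred, table)
        assert scores.seen_auc == 100.0
        assert scores.unseen_auc == 100.0
        assert scores.hm == 100.0

    def test_all_unseen_episode_reports_unseen_as_hm(self):
        episode, table = self.make_episode_and_table()
        episode = g.Episode(
            seen_classes=(),
            unseen_classes=("Alpha", "Gamma"),
            excluded_classes=frozenset({"Beta", "Delta"}),
            trn_ids=episode.trn_ids,
            tst_ids=episode.tst_ids,
            pool="tst",
        )
        labels = episode.label_matrix(table, "tst").astype(float)
        pred = g.PredictionMatrix(
            probs=labels * 0.6 + 0.2, classes=episode.classes,
            record_ids=episode.tst_ids,
        )
        scores = g.score_episode(episode, pred, table)
        assert scores.seen_auc is None
        assert scores.hm == scores.unseen_auc

    def test_misaligned_predictions_rejected(self):
        episode, table = self.make_episode_and_table()
        pred = g.PredictionMatrix(
            probs=np.full((4, 2), 0.5), classes=("Gamma", "Alpha"),
            record_ids=episode.tst_ids,
        )
        with pytest.raises(ValueError, match="classes"):
            g.score_episode(episode, pred, table)

    def test_scrambled_label_control_near_chance(self, balanced_setup):
        """Random predictions average to chance-level scores."""
        _, table, part, split, _ = balanced_setup
        rng = np.random.default_rng(0)
        hms = []
        for _ in range(40):
            episode = g.generate_episode(
                table, split, part, g.EpisodeSpec(2, 1, 5, 5), rng, pool="tst"
            )
            pred = g.PredictionMatrix(
                probs=rng.random((len(episode.tst_ids), episode.n_way)),
                classes=episode.classes, record_ids=episode.tst_ids,
            )
            hms.append(g.score_episode(episode, pred, table).hm)
        assert abs(np.mean(hms) - 50.0) < 6.0


class TestAggregate:
    def test_identical_scores_have_zero_half_width(self):
        scores = [g.EpisodeScores(80.0, 70.0, g.harmonic_mean(80, 70))] * 5
        report = g.aggregate(scores)
        assert report.half_widths["hm"] == 0.0
        assert report.means["seen_auc"] == 80.0

    def test_two_value_closed_form(self):
        from scipy.stats import norm

        scores = [g.EpisodeScores(None, None, 60.0),
                  g.EpisodeScores(None, None, 80.0)]
        report = g.aggregate(scores, level=0.95)
        z = norm.ppf(0.975)
        sd = np.std([60.0, 80.0], ddof=1)
        assert report.means["hm"] == pytest.approx(70.0)
        assert report.half_widths["hm"] == pytest.approx(z * sd / np.sqrt(2))
        assert "seen_auc" not in report.means

    def test_half_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(1)
        population = [g.EpisodeScores(None, None, float(v))
                      for v in rng.normal(70, 8, size=4000)]
        small = g.aggregate(population[:250]).half_widths["hm"]
        large = g.aggregate(population).half_widths["hm"]
        assert large == pytest.approx(small / 4.0, rel=0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            g.aggregate([])


class TestRunGrid:
    def test_grid_shape_matches_way_unseen_structure(self, batchbased_easy,
                                                     easy_setup):
        _, table, part, split, renderer = easy_setup
        frame = g.run_grid(
            batchbased_easy, table, split, part, renderer,
            ways=(3,), n_unseen_values=None, k_values=(2,), k_tst=2,
            episodes_per_cell=2, seed=0,
        )
        # 3-way sweep yields n-unseen 1..3; the 6-class corpus has only two
        # meta-test classes, so the 3-unseen cell is reported as skipped.
        assert len(frame) == 3
        assert (frame["n_unseen"] == [1, 2, 3]).all()
        assert frame.iloc[2]["skipped"] != ""
        assert (frame.iloc[:2]["n_episodes"] == 2).all()

    def test_single_cell_matches_direct_aggregate(self, batchbased_easy,
                                                  easy_setup):
        _, table, part, split, renderer = easy_setup
        seed = 5
        frame = g.run_grid(
            batchbased_easy, table, split, part, renderer,
            ways=(3,), n_unseen_values=(1,), k_values=(3,), k_tst=3,
            episodes_per_cell=3, seed=seed,
        )
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(3, 1, 3))
        )
        scores = []
        for _ in range(3):
            episode = g.generate_episode(
                table, split, part, g.EpisodeSpec(2, 1, 3, 3), rng, pool="tst"
            )
            pred = batchbased_easy.predict_episode(episode, table, renderer,
                                                   rng=rng)
            scores.append(g.score_episode(episode, pred, table))
        direct = g.aggregate(scores)
        assert frame.iloc[0]["hm"] == pytest.approx(direct.means["hm"])
        assert frame.iloc[0]["hm_hw"] == pytest.approx(direct.half_widths["hm"])

    def test_markdown_rendering(self, batchbased_easy, easy_setup):
        _, table, part, split, renderer = easy_setup
        frame = g.run_grid(
            batchbased_easy, table, split, part, renderer,
            ways=(3,), n_unseen_values=(1,), k_values=(2,), k_tst=2,
            episodes_per_cell=2, seed=0,
        )
        text = report_to_markdown(frame)
        assert "| n-way |" in text
        assert "3 | 1 | 2" in text
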