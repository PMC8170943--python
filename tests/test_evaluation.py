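"""Negative sampling, metrics, ROC/AUC, cross-validation and ranking."""

import numpy as np
import pytest

from repogru import (
    ConfusionCounts,
    EntityIndex,
    FeatureConfig,
    InteractionMatrix,
    PipelineConfig,
    TrainConfig,
    confusion_from_scores,
    fit_predictor,
    metrics_from_counts,
    rank_candidates,
    roc_auc,
    sample_negatives,
    tenfold_cv,
    top_n_retrieval,
)
from repogru.evaluation import RankedList
from repogru.synth import SyntheticConfig, generate


def _auc_pairwise_oracle(scores, labels):
    """O(n^2) Mann-Whitney statistic: P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg))


class TestSampleNegatives:
    def test_count_and_distinct_zero_cells(self, small_ds):
        ds, _ = small_ds
        pairs = sample_negatives(ds.interactions, 1.0, seed=4)
        assert len(pairs) == ds.interactions.n_interactions
        assert len({tuple(p) for p in pairs}) == len(pairs)
        assert (ds.interactions.values[pairs[:, 0], pairs[:, 1]] == 0).all()

    def test_seed_reproducible(self, small_ds):
        ds, _ = small_ds
        a = sample_negatives(ds.interactions, 1.0, seed=4)
        b = sample_negatives(ds.interactions, 1.0, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_all_ones_matrix_rejected(self):
        I = InteractionMatrix(
            np.ones((2, 2), dtype=int), EntityIndex(("a", "b")), EntityIndex(("x", "y"))
        )
        with pytest.raises(ValueError, match="zero cells"):
            sample_negatives(I, 1.0, seed=0)


class TestMetrics:
    def test_balanced_example(self):
        m = metrics_from_counts(ConfusionCounts(tp=3, tn=3, fp=1, fn=1))
        assert m.acc == pytest.approx(0.75)
        assert m.tpr == pytest.approx(0.75)
        assert m.tnr == pytest.approx(0.75)
        assert m.ppv == pytest.approx(0.75)
        assert m.mcc == pytest.approx(0.5)

    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(tp=5, tn=7, fp=0, fn=0))
        assert (m.acc, m.tpr, m.tnr, m.ppv, m.mcc) == (1, 1, 1, 1, 1)

    def test_zero_denominator_flagged_not_raised(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, tn=4, fp=0, fn=0))
        assert m.ppv == 0.0 and "ppv" in m.degenerate
        assert m.mcc == 0.0 and "mcc" in m.degenerate

    def test_matches_per_sample_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 60)
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            # brute-force per-sample counting
            tp = sum(1 for s, l in zip(scores, labels) if s >= 0.5 and l == 1)
            tn = sum(1 for s, l in zip(scores, labels) if s < 0.5 and l == 0)
            fp = sum(1 for s, l in zip(scores, labels) if s >= 0.5 and l == 0)
            fn = sum(1 for s, l in zip(scores, labels) if s < 0.5 and l == 1)
            c = confusion_from_scores(scores, labels)
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
            m = metrics_from_counts(c)
            if tp + fn:
                assert m.tpr == tp / (tp + fn)
            if tp + fp:
                assert m.ppv == tp / (tp + fp)
            assert m.acc == (tp + tn) / n


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 300))
            scores = np.round(rng.random(n), 2)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(_auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


@pytest.fixture(scope="module")
def cv_report(small_ds):
    ds, _ = small_ds
    cfg = PipelineConfig(
        features=FeatureConfig(tsvd_dim=16),
        train=TrainConfig(hidden=16, epochs=5, batch_size=32),
    )
    return tenfold_cv(ds, cfg, seed=2), ds


class TestTenfoldCv:
    def test_folds_partition_samples(self, cv_report):
        report, _ = cv_report
        n = len(report.labels)
        sizes = np.bincount(report.fold_assignment, minlength=10)
        assert sizes.sum() == n and len(sizes) == 10
        assert sizes.max() - sizes.min() <= 1

    def test_mean_and_sd_are_over_folds(self, cv_report):
        report, _ = cv_report
        aucs = [f.auc for f in report.folds]
        assert report.mean["auc"] == pytest.approx(np.mean(aucs))
        assert report.sd["auc"] == pytest.approx(np.std(aucs))  # population sd

    def test_report_frame_layout(self, cv_report):
        report, _ = cv_report
        df = report.to_frame()
        assert list(df["fold"])[:10] == [str(i) for i in range(1, 11)]
        assert list(df["fold"])[10:] == ["mean", "sd"]
        assert df.loc[10, "acc"] == pytest.approx(100 * report.mean["acc"])

    def test_too_few_samples_rejected(self, toy_ds):
        with pytest.raises(ValueError, match="per class"):
            tenfold_cv(toy_ds, PipelineConfig(), seed=0)

    def test_fold_assignment_reproducible(self, small_ds):
        ds, _ = small_ds
        cfg = PipelineConfig(
            features=FeatureConfig(tsvd_dim=8),
            train=TrainConfig(hidden=4, epochs=1, batch_size=64),
        )
        r1 = tenfold_cv(ds, cfg, seed=3)
        r2 = tenfold_cv(ds, cfg, seed=3)
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)
        assert [f.auc for f in r1.folds] == [f.auc for f in r2.folds]


class TestRanking:
    def test_constant_scores_rank_by_candidate_id(self):
        rl = RankedList(
            "Q", ["c3", "c1", "c2"], np.array([0.5, 0.5, 0.5]), np.array([0, 1, 0])
        )
        assert rl.candidate_ids == ["c1", "c2", "c3"]
        np.testing.assert_array_equal(rl.ranks, [1, 2, 3])

    def test_row_count_and_known_flags(self, small_ds, fast_cfg):
        ds, _ = small_ds
        fitted = fit_predictor(ds, fast_cfg, seed=0)
        ranked = rank_candidates(ds, fitted, ds.drugs.ids[0])
        assert len(ranked) == ds.n_diseases
        assert ranked.known.sum() == ds.interactions.values[0].sum()

    def test_unknown_query_rejected(self, small_ds, fast_cfg):
        ds, _ = small_ds
        fitted = fit_predictor(ds, fast_cfg, seed=0)
        with pytest.raises(KeyError, match="NOPE"):
            rank_candidates(ds, fitted, "NOPE")

    def test_block_partners_rank_highly(self):
        # strong planted structure: the query drug's block diseases should
        # dominate the top of the list
        ds, truth = generate(
            SyntheticConfig(m=60, n=40, k_blocks=3, p_in=0.6, p_out=0.01, seed=2)
        )
        cfg = PipelineConfig(
            features=FeatureConfig(tsvd_dim=16),
            train=TrainConfig(hidden=16, epochs=20, batch_size=32),
        )
        fitted = fit_predictor(ds, cfg, seed=0)
        qi = 0
        ranked = rank_candidates(ds, fitted, ds.drugs.ids[qi])
        block = truth.drug_blocks[qi]
        partner_ids = {
            ds.diseases.ids[j]
            for j in np.flatnonzero(truth.disease_blocks == block)
        }
        ranks = [r for r, cid in zip(ranked.ranks, ranked.candidate_ids)
                 if cid in partner_ids]
        assert np.median(ranks) <= 0.25 * ds.n_diseases


class TestTopN:
    @staticmethod
    def _ranked(scores, known):
        ids = [f"c{i:03d}" for i in range(len(scores))]
        return RankedList("Q", ids, np.asarray(scores), np.asarray(known))

    def test_saturation_counts_all_known(self):
        rl = self._ranked([0.9, 0.4, 0.6], [1, 0, 1])
        assert top_n_retrieval(rl, 3) == 2

    def test_oracle_scores_retrieve_perfectly(self):
        known = np.array([1, 1, 0, 0, 1, 0])
        rl = self._ranked(known.astype(float), known)
        for k in (1, 2, 3):
            assert top_n_retrieval(rl, k) == k

    def test_clamped_with_warning(self, caplog):
        rl = self._ranked([0.1, 0.2], [0, 1])
        with caplog.at_level("WARNING"):
            assert top_n_retrieval(rl, 10) == 1
        assert "clamp" in caplog.text.lower()

    def test_random_scores_match_hypergeometric_expectation(self):
        rng = np.random.default_rng(0)
        n_cand, n_known, top = 50, 12, 10
        counts = []
        for _ in range(200):
            known = np.zeros(n_cand, dtype=int)
            known[rng.choice(n_cand, n_known, replace=False)] = 1
            counts.append(top_n_retrieval(self._ranked(rng.random(n_cand), known), top))
        expected = top * n_known / n_cand
        se = np.sqrt(top * (n_known / n_cand) * (1 - n_known / n_cand) / 200)
        assert abs(np.mean(counts) - expected) <= 3.5 * se
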