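"""Metrics vs brute-force oracles, split plans, CV leakage, optimization protocol."""

import math

import numpy as np
import pytest

from beepro.evaluate import (
    ConfusionCounts,
    OptimizationGrids,
    auc,
    confusion,
    cross_validate,
    evaluate_predictions,
    make_split,
    metrics,
    single_representation_cv,
    three_way_optimize,
    window_sweep,
)
from beepro.features import WindowConfig
from beepro.model import SVMConfig
from beepro.scales import (
    compute_normalized_aar,
    custom_feature_set,
    get_feature_set,
)
from beepro.synthetic import planted_feature_dataset, planted_recovery_spec


def oracle_metrics(tp, tn, fp, fn):
    """Direct evaluation of the confusion-metric formulas (None = undefined)."""
    out = {}
    out["sen"] = tp / (tp + fn) if tp + fn else None
    out["spe"] = tn / (tn + fp) if tn + fp else None
    out["acc"] = (tp + tn) / (tp + tn + fp + fn)
    out["ppv"] = tp / (tp + fp) if tp + fp else None
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = (tp * tn - fp * fn) / den if den else None
    return out


def oracle_auc(labels, scores):
    """All-pairs count: P(pos > neg) + 1/2 P(pos == neg)."""
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        labels = np.array([1] * 3 + [-1] * 7)
        c = confusion(labels, labels)
        assert (c.TP, c.TN, c.FP, c.FN) == (3, 7, 0, 0)

    def test_all_negative_predictions(self):
        labels = np.array([1, 1, -1, -1])
        c = confusion(labels, np.full(4, -1))
        assert c.FN == 2 and c.TN == 2 and c.TP == 0

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(5)
        labels = rng.choice([-1, 1], size=200)
        preds = rng.choice([-1, 1], size=200)
        c = confusion(labels, preds)
        tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for l, p in zip(labels, preds):
            key = ("T" if l == p else "F") + ("P" if p == 1 else "N")
            tally[key] += 1
        assert (c.TP, c.TN, c.FP, c.FN) == tuple(tally[k] for k in ("TP", "TN", "FP", "FN"))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.array([1, -1]), np.array([1]))


class TestMetrics:
    def test_perfect_classifier(self):
        rep = metrics(ConfusionCounts(10, 90, 0, 0))
        assert rep.sen == rep.spe == rep.acc == rep.ppv == rep.mcc == 1.0
        assert not rep.undefined

    def test_worked_example(self):
        rep = metrics(ConfusionCounts(TP=8, FN=2, TN=85, FP=5))
        expected = oracle_metrics(8, 85, 5, 2)
        assert rep.sen == pytest.approx(0.8)
        assert rep.spe == pytest.approx(85 / 90)
        assert rep.acc == pytest.approx(0.93)
        assert rep.ppv == pytest.approx(8 / 13)
        assert rep.mcc == pytest.approx(expected["mcc"], abs=1e-14)

    def test_zero_denominator_flagged_not_zeroed(self):
        rep = metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=3))
        assert "ppv" in rep.undefined
        assert math.isnan(rep.ppv)
        assert "mcc" in rep.undefined

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            rep = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            exp = oracle_metrics(int(tp), int(tn), int(fp), int(fn))
            for key, val in exp.items():
                got = getattr(rep, key)
                if val is None:
                    assert key in rep.undefined and math.isnan(got)
                else:
                    assert got == pytest.approx(val, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        labels = np.array([1, 1, -1, -1])
        assert auc(labels, np.array([3.0, 2.0, 1.0, 0.0])) == 1.0

    def test_all_ties_give_half(self):
        labels = np.array([1, -1, 1, -1])
        assert auc(labels, np.zeros(4)) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.ones(5), np.arange(5.0))

    def test_random_instances_match_all_pairs_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            labels = rng.choice([-1, 1], size=n)
            if np.unique(labels).size < 2:
                continue
            scores = rng.choice(np.linspace(-1, 1, 7), size=n)  # forces ties
            assert auc(labels, scores) == pytest.approx(
                oracle_auc(labels, scores), abs=1e-12
            )


class TestSplit:
    def test_partition_properties(self, small_enriched):
        plan = make_split(small_enriched, k=5, seed=1)
        all_ids = [i for part in plan.parts for i in part]
        assert sorted(all_ids) == sorted(small_enriched.ids)
        assert len(plan.parts) == 5
        sizes = [len(p) for p in plan.parts]
        assert max(sizes) - min(sizes) <= 1  # round-robin balance

    def test_deterministic_given_seed(self, small_enriched):
        assert make_split(small_enriched, seed=9) == make_split(small_enriched, seed=9)

    def test_different_seeds_differ(self, small_enriched):
        assert make_split(small_enriched, seed=1) != make_split(small_enriched, seed=2)

    def test_too_few_proteins(self, toy_dataset):
        with pytest.raises(ValueError):
            make_split(toy_dataset, k=5, seed=0)


@pytest.fixture(scope="module")
def cv_result(small_enriched):
    fs = get_feature_set(("AAR", "PARJ860101", "KYTJ820101", "LEVM780101"))
    return cross_validate(
        small_enriched, fs, WindowConfig(w=9, f=0.04),
        SVMConfig(c=1, gamma=1, weight_pos=5), seed=13,
    )


class TestCrossValidation:

    def test_fold_scales_fitted_on_training_parts_only(self, small_enriched, cv_result):
        """Leakage guard: each fold's AAR equals the AAR recomputed from its
        recorded training proteins, and differs from the global AAR."""
        global_aar = compute_normalized_aar(small_enriched).as_array()
        for fold in cv_result.folds:
            expected = compute_normalized_aar(
                small_enriched.subset(fold.train_ids)
            ).as_array()
            assert np.array_equal(fold.model.aar_scale.as_array(), expected)
            assert not np.array_equal(fold.model.aar_scale.as_array(), global_aar)
            assert set(fold.model.provenance["train_ids"]) == set(fold.train_ids)
            assert not set(fold.train_ids) & set(fold.test_ids)

    def test_pooled_confusion_is_sum_of_fold_confusions(self, cv_result):
        totals = np.array([
            [f.report.counts.TP, f.report.counts.TN,
             f.report.counts.FP, f.report.counts.FN]
            for f in cv_result.folds if not f.failed
        ]).sum(axis=0)
        pooled = cv_result.pooled.counts
        assert tuple(totals) == (pooled.TP, pooled.TN, pooled.FP, pooled.FN)

    def test_every_residue_scored_once(self, small_enriched, cv_result):
        assert cv_result.pooled.counts.total == small_enriched.total_residues


class TestWindowSweep:
    def test_table_shape_and_consistency(self, small_enriched):
        table = window_sweep(small_enriched, "AAR", w_values=(5, 9), seed=13)
        assert list(table["w"]) == [5, 9]
        direct = single_representation_cv(
            small_enriched, "AAR", WindowConfig(w=5, f=0.0),
            plan=make_split(small_enriched, k=5, seed=13),
        )
        assert table["auc"].iloc[0] == pytest.approx(direct)

    def test_rejects_bad_window(self, small_enriched):
        with pytest.raises(ValueError):
            window_sweep(small_enriched, "AAR", w_values=(4,))


@pytest.fixture(scope="module")
def planted():
    return planted_feature_dataset(planted_recovery_spec(seed=23), n_decoy_scales=5)


@pytest.fixture(scope="module")
def threeway_result(planted):
    grids = OptimizationGrids(
        w_values=(11,), c_values=(1.0,), gamma_values=(1.0,),
        weight_pos_values=(5.0,), f_values=(0.0,), feature_selection=True,
    )
    fs = custom_feature_set("planted6", planted.all_scales)
    return three_way_optimize(planted.dataset, fs, grids=grids, seed=7)


class TestThreeWay:

    def test_validation_auc_nondecreasing_along_steps(self, threeway_result):
        for it in threeway_result.iterations:
            aucs = [step[2] for step in it.trace]
            assert aucs == sorted(aucs)

    def test_informative_feature_retained_in_every_iteration(self, threeway_result):
        for it in threeway_result.iterations:
            assert "PLANTED_INFORMATIVE" in it.feature_set.names

    def test_test_parts_rotate_and_cover(self, threeway_result):
        assert sorted(it.test_part for it in threeway_result.iterations) == [0, 1, 2, 3, 4]
        for it in threeway_result.iterations:
            assert it.validation_part != it.test_part
            assert it.validation_part not in it.train_part_ids

    def test_degenerate_grids_freeze_configuration(self, threeway_result):
        for it in threeway_result.iterations:
            assert it.window.w == 11
            assert it.svm.c == 1.0 and it.svm.weight_pos == 5.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            OptimizationGrids(w_values=())
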