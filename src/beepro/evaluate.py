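"""Evaluation protocols: confusion metrics, AUC, five-fold cross-validation,
window sweeps, and the three-way data-split optimization procedure.

Two leakage rules are enforced by construction and recorded in fold
provenance: the amino-acid-ratio scale and the [-1, 1] feature scaler are
re-fitted for every fold from its training proteins only, and splits are made
at the protein level so overlapping windows of one protein never straddle
train and test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import (
    ALLOWED_F,
    ALLOWED_WINDOWS,
    FeatureMatrix,
    WindowConfig,
    apply_scaler,
    fit_scaler,
    hybrid_vectors,
    pssm_vectors,
    single_scale_vectors,
    stack,
)
from .io_datasets import AntigenRecord, EpitopeDataset
from .model import SingleClassError, SVMConfig, predict_decision, predict_labels, train_svm
from .pssm import PSSMatrix, pseudo_pssm
from .scales import FeatureSet, PropensityScale, compute_normalized_aar

PSSMSource = Callable[[AntigenRecord], PSSMatrix]


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """SEN/SPE/ACC/PPV/MCC plus threshold-free AUC for one evaluation.

    A metric whose defining ratio has a zero denominator is NaN and its name
    appears in ``undefined`` instead of being silently reported as 0.
    """

    counts: ConfusionCounts
    sen: float
    spe: float
    acc: float
    ppv: float
    mcc: float
    auc: float = float("nan")
    undefined: frozenset = frozenset()

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "acc": self.acc, "sen": self.sen,
            "spe": self.spe, "mcc": self.mcc, "ppv": self.ppv,
            "TP": self.counts.TP, "TN": self.counts.TN,
            "FP": self.counts.FP, "FN": self.counts.FN,
        }


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """2x2 tally of +/-1 labels vs +/-1 predictions (+1 is the positive class)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {labels.shape} labels vs {predictions.shape} predictions"
        )
    pos, ppos = labels == 1, predictions == 1
    return ConfusionCounts(
        TP=int(np.sum(pos & ppos)),
        TN=int(np.sum(~pos & ~ppos)),
        FP=int(np.sum(~pos & ppos)),
        FN=int(np.sum(pos & ~ppos)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Confusion-derived metrics; zero-denominator metrics flagged undefined."""
    if counts.total == 0:
        raise ValueError("no evaluated residues")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    undefined = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    sen = ratio(tp, tp + fn, "sen")
    spe = ratio(tn, tn + fp, "spe")
    acc = (tp + tn) / counts.total
    ppv = ratio(tp, tp + fp, "ppv")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den == 0:
        undefined.add("mcc")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(counts, sen, spe, acc, ppv, mcc,
                         undefined=frozenset(undefined))


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count 1/2 per tied pair."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels == 1, scores))


def evaluate_predictions(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.0
) -> MetricsReport:
    """Full report from continuous scores: confusion at the threshold, plus AUC."""
    predictions = np.where(np.asarray(scores) > threshold, 1, -1)
    report = metrics(confusion(labels, predictions))
    return replace(report, auc=auc(labels, scores))


# ---------------------------------------------------------------------------
# Splitting


@dataclass(frozen=True)
class SplitPlan:
    """Protein-level partition of a dataset into k parts."""

    parts: tuple[tuple[str, ...], ...]
    seed: int
    mode: str = "fivefold"

    def __post_init__(self) -> None:
        if self.mode not in ("fivefold", "threeway"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "threeway" and len(self.parts) != 5:
            raise ValueError("three-way protocol requires exactly 5 parts")
        all_ids = [i for part in self.parts for i in part]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split parts overlap")

    @property
    def k(self) -> int:
        return len(self.parts)

    def train_ids(self, fold: int) -> tuple[str, ...]:
        return tuple(
            i for j, part in enumerate(self.parts) if j != fold for i in part
        )


def make_split(
    dataset: EpitopeDataset, k: int = 5, seed: int = 0, mode: str = "fivefold"
) -> SplitPlan:
    """Shuffle proteins with the seed and deal them round-robin into k parts."""
    ids = dataset.ids
    if len(ids) < k:
        raise ValueError(f"{len(ids)} proteins cannot fill {k} parts")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    parts: list[list[str]] = [[] for _ in range(k)]
    for i, rid in enumerate(order):
        parts[i % k].append(rid)
    return SplitPlan(tuple(tuple(p) for p in parts), seed=seed, mode=mode)


# ---------------------------------------------------------------------------
# Featurization shared by the protocols


def _pssm_cache(
    records: Iterable[AntigenRecord], source: PSSMSource
) -> dict[str, PSSMatrix]:
    return {rec.id: source(rec) for rec in records}


def _featurize_hybrid(
    records: Sequence[AntigenRecord],
    feature_set: FeatureSet,
    window: WindowConfig,
    aar_scale: PropensityScale | None,
    pssms: dict[str, PSSMatrix],
) -> FeatureMatrix:
    return stack([
        hybrid_vectors(
            rec, feature_set, window,
            aar_scale=aar_scale,
            pssm_matrix=pssms.get(rec.id),
        )
        for rec in records
    ])


def _fit_fold(
    train_records: Sequence[AntigenRecord],
    feature_set: FeatureSet,
    window: WindowConfig,
    svm: SVMConfig,
    pssms: dict[str, PSSMatrix],
    pseudocount: float,
    provenance: dict,
):
    """AAR + scaler + SVM fitted on training records only."""
    aar = None
    if feature_set.include_aar:
        train_ds = EpitopeDataset(list(train_records), name="fold-train")
        aar = compute_normalized_aar(train_ds, pseudocount)
    train_fm = _featurize_hybrid(train_records, feature_set, window, aar, pssms)
    scaler = fit_scaler(train_fm)
    model = train_svm(
        apply_scaler(scaler, train_fm), svm,
        scaler=scaler, aar_scale=aar, provenance=provenance,
    )
    return model


def _score_records(
    model, records: Sequence[AntigenRecord],
    feature_set: FeatureSet, window: WindowConfig,
    pssms: dict[str, PSSMatrix],
) -> tuple[np.ndarray, np.ndarray]:
    fm = _featurize_hybrid(records, feature_set, window, model.aar_scale, pssms)
    scaled = apply_scaler(model.scaler, fm)
    return predict_decision(model, scaled), scaled.labels


# ---------------------------------------------------------------------------
# Five-fold cross-validation


@dataclass
class FoldResult:
    index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    model: object | None = None
    report: MetricsReport | None = None
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None
    failed: bool = False
    failure: str = ""


@dataclass
class CrossValidationResult:
    folds: list[FoldResult]
    pooled: MetricsReport
    fold_mean: dict

    @property
    def n_failed(self) -> int:
        return sum(f.failed for f in self.folds)


def _nanmean_reports(reports: Sequence[MetricsReport]) -> dict:
    keys = ("auc", "acc", "sen", "spe", "mcc", "ppv")
    return {
        k: float(np.nanmean([getattr(r, k) for r in reports])) for k in keys
    }


def cross_validate(
    dataset: EpitopeDataset,
    feature_set: FeatureSet,
    window: WindowConfig = WindowConfig(),
    svm: SVMConfig = SVMConfig(),
    pssm_source: PSSMSource = pseudo_pssm,
    plan: SplitPlan | None = None,
    seed: int = 0,
    pseudocount: float = 1.0,
    threshold: float = 0.0,
) -> CrossValidationResult:
    """k-fold protein-level cross-validation of the hybrid model.

    For each fold the AAR scale, the feature scaler and the SVM are fitted on
    the training proteins only; held-out residues are scored once.  Metrics
    are reported per fold and pooled over all held-out predictions
    (micro-average); the per-fold mean is also returned.  A fold whose
    training residues collapse to a single class is marked failed and the run
    continues.
    """
    if plan is None:
        plan = make_split(dataset, k=5, seed=seed)
    pssms = (
        _pssm_cache(dataset, pssm_source) if feature_set.include_pssm else {}
    )
    folds: list[FoldResult] = []
    for i in range(plan.k):
        test_ids = plan.parts[i]
        train_ids = plan.train_ids(i)
        fold = FoldResult(i, train_ids, test_ids)
        train_records = [dataset[rid] for rid in train_ids]
        test_records = [dataset[rid] for rid in test_ids]
        try:
            model = _fit_fold(
                train_records, feature_set, window, svm, pssms, pseudocount,
                provenance={"fold": i, "train_ids": list(train_ids)},
            )
            scores, labels = _score_records(
                model, test_records, feature_set, window, pssms
            )
        except SingleClassError as exc:
            fold.failed, fold.failure = True, str(exc)
            folds.append(fold)
            continue
        fold.model = model
        fold.scores, fold.labels = scores, labels
        fold.report = evaluate_predictions(labels, scores, threshold)
        folds.append(fold)

    scored = [f for f in folds if not f.failed]
    if not scored:
        raise SingleClassError("every fold failed with single-class training data")
    pooled = evaluate_predictions(
        np.concatenate([f.labels for f in scored]),
        np.concatenate([f.scores for f in scored]),
        threshold,
    )
    return CrossValidationResult(
        folds=folds,
        pooled=pooled,
        fold_mean=_nanmean_reports([f.report for f in scored]),
    )


# ---------------------------------------------------------------------------
# Single-scale / PSSM window sweep


def _single_fold_matrices(
    records: Sequence[AntigenRecord],
    representation: str | PropensityScale,
    window: WindowConfig,
    aar_scale: PropensityScale | None,
    pssms: dict[str, PSSMatrix],
) -> FeatureMatrix:
    mats = []
    for rec in records:
        if representation == "PSSM":
            mats.append(pssm_vectors(rec, pssms[rec.id], window))
        elif representation == "AAR":
            mats.append(single_scale_vectors(rec, aar_scale, window))
        else:
            mats.append(single_scale_vectors(rec, representation, window))
    return stack(mats)


def single_representation_cv(
    dataset: EpitopeDataset,
    representation: str | PropensityScale,
    window: WindowConfig,
    svm: SVMConfig | None = None,
    pssm_source: PSSMSource = pseudo_pssm,
    plan: SplitPlan | None = None,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> float:
    """Pooled cross-validated AUC for one single-scale (or PSSM) representation.

    ``representation`` is ``"AAR"`` (recomputed per fold), ``"PSSM"``, or a
    fixed :class:`PropensityScale`.  The default SVM setting is the
    single-scale protocol (w+1=20, C=1, gamma=1/n_features).
    """
    if plan is None:
        plan = make_split(dataset, k=5, seed=seed)
    pssms = _pssm_cache(dataset, pssm_source) if representation == "PSSM" else {}
    all_scores, all_labels = [], []
    for i in range(plan.k):
        train_records = [dataset[rid] for rid in plan.train_ids(i)]
        test_records = [dataset[rid] for rid in plan.parts[i]]
        aar = None
        if representation == "AAR":
            aar = compute_normalized_aar(
                EpitopeDataset(train_records, name="fold-train"), pseudocount
            )
        train_fm = _single_fold_matrices(train_records, representation, window, aar, pssms)
        test_fm = _single_fold_matrices(test_records, representation, window, aar, pssms)
        fold_svm = svm or SVMConfig.single_scale_protocol(train_fm.row_width)
        scaler = fit_scaler(train_fm)
        model = train_svm(apply_scaler(scaler, train_fm), fold_svm, scaler=scaler)
        all_scores.append(predict_decision(model, apply_scaler(scaler, test_fm)))
        all_labels.append(test_fm.labels)
    return auc(np.concatenate(all_labels), np.concatenate(all_scores))


def window_sweep(
    dataset: EpitopeDataset,
    representation: str | PropensityScale,
    w_values: Sequence[int] = ALLOWED_WINDOWS,
    svm: SVMConfig | None = None,
    pssm_source: PSSMSource = pseudo_pssm,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Cross-validated AUC per window size for one representation.

    Reproduces the shape of the single-scale window-size experiments; the
    same split plan is reused across window sizes.
    """
    bad = set(w_values) - set(ALLOWED_WINDOWS)
    if bad:
        raise ValueError(f"window sizes outside odd 5..29: {sorted(bad)}")
    plan = make_split(dataset, k=5, seed=seed)
    rows = []
    for w in w_values:
        value = single_representation_cv(
            dataset, representation, WindowConfig(w=w, f=0.0),
            svm=svm, pssm_source=pssm_source, plan=plan, pseudocount=pseudocount,
        )
        rows.append({"w": w, "auc": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Three-way data-split optimization


@dataclass(frozen=True)
class OptimizationGrids:
    """Search grids for the six ordered optimization steps."""

    w_values: tuple[int, ...] = ALLOWED_WINDOWS
    c_values: tuple[float, ...] = (0.1, 1.0, 10.0)
    gamma_values: tuple[float, ...] = (0.1, 1.0, 10.0)
    weight_pos_values: tuple[float, ...] = (1.0, 5.0, 10.0, 15.0, 20.0)
    f_values: tuple[float, ...] = ALLOWED_F
    feature_selection: bool = True

    def __post_init__(self) -> None:
        for name in ("w_values", "c_values", "gamma_values",
                     "weight_pos_values", "f_values"):
            if not getattr(self, name):
                raise ValueError(f"empty grid {name}")


@dataclass
class IterationResult:
    index: int
    train_part_ids: tuple[int, ...]
    validation_part: int
    test_part: int
    window: WindowConfig
    svm: SVMConfig
    feature_set: FeatureSet
    trace: list = field(default_factory=list)
    validation_auc: float = float("nan")
    test_report: MetricsReport | None = None
    test_scores: np.ndarray | None = None
    test_labels: np.ndarray | None = None


@dataclass
class ThreeWayResult:
    iterations: list[IterationResult]
    mean_test: dict
    pooled_test: MetricsReport

    @property
    def best(self) -> IterationResult:
        return max(self.iterations, key=lambda it: it.validation_auc)


def three_way_optimize(
    dataset: EpitopeDataset,
    candidate_features: FeatureSet,
    grids: OptimizationGrids = OptimizationGrids(),
    pssm_source: PSSMSource = pseudo_pssm,
    plan: SplitPlan | None = None,
    seed: int = 0,
    pseudocount: float = 1.0,
    threshold: float = 0.0,
) -> ThreeWayResult:
    """Greedy six-step optimization on a 5-part three-way split.

    The dataset is split into five protein-level parts.  In each of five
    iterations the parts rotate through the roles 3x train / 1x validation /
    1x test.  Within an iteration the six steps run in order — (1) window
    size, (2) C and gamma, (3) positive-class weight, (4) backward feature
    elimination, (5) weighting factor f, (6) re-optimization of the
    positive-class weight — each selecting by validation AUC with earlier
    choices frozen; ties break toward the simpler configuration.  The test
    part is scored exactly once per iteration, by a model retrained on the
    train+validation parts with the final configuration.
    """
    if plan is None:
        plan = make_split(dataset, k=5, seed=seed, mode="threeway")
    if plan.k != 5:
        raise ValueError("three-way optimization requires a 5-part plan")
    pssms = (
        _pssm_cache(dataset, pssm_source)
        if candidate_features.include_pssm else {}
    )

    def val_auc(train_records, val_records, fs, window, svm) -> float:
        try:
            model = _fit_fold(train_records, fs, window, svm, pssms,
                              pseudocount, provenance={})
            scores, labels = _score_records(model, val_records, fs, window, pssms)
            return auc(labels, scores)
        except (SingleClassError, ValueError):
            return float("-inf")

    iterations: list[IterationResult] = []
    for t in range(5):
        test_part, val_part = t, (t + 1) % 5
        train_parts = tuple(j for j in range(5) if j not in (test_part, val_part))
        train_records = [
            dataset[rid] for j in train_parts for rid in plan.parts[j]
        ]
        val_records = [dataset[rid] for rid in plan.parts[val_part]]
        test_records = [dataset[rid] for rid in plan.parts[test_part]]

        fs = candidate_features
        w = grids.w_values[0]
        f = min(grids.f_values)
        c, gamma = min(grids.c_values), min(grids.gamma_values)
        wpos = min(grids.weight_pos_values)
        trace: list[tuple[str, object, float]] = []
        current = float("-inf")

        def cfg(c=None, gamma=None, wpos_=None):
            return SVMConfig(
                c=c if c is not None else 1.0,
                gamma=gamma if gamma is not None else 1.0,
                weight_pos=wpos_ if wpos_ is not None else 1.0,
                weight_neg=1.0,
            )

        def evaluate(fs_, w_, f_, c_, g_, wp_):
            return val_auc(
                train_records, val_records, fs_,
                WindowConfig(w=w_, f=f_), cfg(c_, g_, wp_),
            )

        # (1) window size
        best_w, current = None, float("-inf")
        for cand in sorted(set(grids.w_values)):
            score = evaluate(fs, cand, f, c, gamma, wpos)
            if score > current:
                best_w, current = cand, score
        if best_w is None:
            raise SingleClassError(
                f"iteration {t}: training or validation part lacks both "
                f"classes for every window size"
            )
        w = best_w
        trace.append(("window", w, current))

        # (2) C and gamma
        for cc, gg in itertools.product(
            sorted(set(grids.c_values)), sorted(set(grids.gamma_values))
        ):
            if (cc, gg) == (c, gamma):
                continue
            score = evaluate(fs, w, f, cc, gg, wpos)
            if score > current:
                c, gamma, current = cc, gg, score
        trace.append(("c_gamma", (c, gamma), current))

        # (3) positive-class weight
        for wp in sorted(set(grids.weight_pos_values)):
            if wp == wpos:
                continue
            score = evaluate(fs, w, f, c, gamma, wp)
            if score > current:
                wpos, current = wp, score
        trace.append(("weight_pos", wpos, current))

        # (4) backward feature elimination, candidate order = feature order;
        # a removal is accepted only if validation AUC does not decrease
        if grids.feature_selection:
            for name in candidate_features.names:
                if name not in fs.names or fs.n_features <= 1:
                    continue
                candidate = fs.drop(name)
                score = evaluate(candidate, w, f, c, gamma, wpos)
                if score >= current:
                    fs, current = candidate, score
            trace.append(("features", fs.names, current))

        # (5) weighting factor f
        for ff in sorted(set(grids.f_values)):
            if ff == f:
                continue
            score = evaluate(fs, w, ff, c, gamma, wpos)
            if score > current:
                f, current = ff, score
        trace.append(("f", f, current))

        # (6) re-optimization of the positive-class weight
        for wp in sorted(set(grids.weight_pos_values)):
            if wp == wpos:
                continue
            score = evaluate(fs, w, f, c, gamma, wp)
            if score > current:
                wpos, current = wp, score
        trace.append(("weight_pos_2", wpos, current))

        window = WindowConfig(w=w, f=f)
        svm = cfg(c, gamma, wpos)
        final_model = _fit_fold(
            train_records + val_records, fs, window, svm, pssms, pseudocount,
            provenance={"iteration": t, "role": "final"},
        )
        scores, labels = _score_records(
            final_model, test_records, fs, window, pssms
        )
        iterations.append(IterationResult(
            index=t,
            train_part_ids=train_parts,
            validation_part=val_part,
            test_part=test_part,
            window=window,
            svm=svm,
            feature_set=fs,
            trace=trace,
            validation_auc=current,
            test_report=evaluate_predictions(labels, scores, threshold),
            test_scores=scores,
            test_labels=labels,
        ))

    # each part is tested exactly once across the five rotations, so pooling
    # the per-iteration test predictions covers the whole dataset
    pooled = evaluate_predictions(
        np.concatenate([it.test_labels for it in iterations]),
        np.concatenate([it.test_scores for it in iterations]),
        threshold,
    )
    return ThreeWayResult(
        iterations=iterations,
        mean_test=_nanmean_reports([it.test_report for it in iterations]),
        pooled_test=pooled,
    )


def metrics_table(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Named metric reports as a DataFrame (for TSV emission)."""
    return pd.DataFrame(
        [{"name": name, **rep.as_dict()} for name, rep in reports.items()]
    )
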