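"""Evaluation protocol and metrics for the three-class expression problem.

Implements the study protocol end to end: stratified partition into *m*
parts, inner cross-validated hyperparameter selection on *m-1* parts, one
held-out part for testing, repeated *n* times with mean +/- SD reporting;
micro-averaged F1 for the three-class task; binary reduction (soluble vs
the rest) with F score, precision, recall, ROC and PRC with trapezoid AUCs;
paired Student's t-test between methods; and Yule's Q diversity statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import classifiers as clf
from .classifiers import LABELS, SOLUBLE, ModelHyperparams

__all__ = [
    "ConfusionCounts",
    "BinaryCounts",
    "PairedOutcomeCounts",
    "CurvePoint",
    "EvalReport",
    "confusion_counts",
    "f1_measure",
    "macro_f1",
    "precision",
    "recall",
    "f_score",
    "roc_prc",
    "yules_q",
    "yules_q_between",
    "stratified_partition",
    "select_hyperparams",
    "repeated_holdout",
    "per_vector_protocol",
    "paired_t_test",
    "DEFAULT_GRID",
]

# LIBSVM-guide style log2 grid (C in 2^-3..2^7, gamma in 2^-9..2^1)
DEFAULT_GRID: list[ModelHyperparams] = [
    ModelHyperparams(C=2.0**lc, gamma=2.0**lg)
    for lc in range(-3, 8, 2)
    for lg in range(-9, 2, 2)
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class correct (A_j), wrongly-assigned-to (B_j), missed (C_j) counts."""

    classes: tuple[str, ...]
    A: tuple[int, ...]
    B: tuple[int, ...]
    C: tuple[int, ...]

    @property
    def n(self) -> int:
        return sum(self.A) + sum(self.C)


def confusion_counts(y_true, y_pred, classes=LABELS) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    A, B, C = [], [], []
    for cls in classes:
        A.append(int(np.sum((y_true == cls) & (y_pred == cls))))
        B.append(int(np.sum((y_true != cls) & (y_pred == cls))))
        C.append(int(np.sum((y_true == cls) & (y_pred != cls))))
    return ConfusionCounts(classes=tuple(classes), A=tuple(A), B=tuple(B), C=tuple(C))


def f1_measure(cc: ConfusionCounts) -> float:
    """Micro-averaged F1 over classes: 2*sum A / (2*sum A + sum B + sum C)."""
    a, b, c = sum(cc.A), sum(cc.B), sum(cc.C)
    denom = 2 * a + b + c
    if denom == 0:
        return 0.0
    return 2 * a / denom


def macro_f1(cc: ConfusionCounts) -> float:
    """Per-class F1 averaged with equal class weight (alternative reading)."""
    vals = []
    for a, b, c in zip(cc.A, cc.B, cc.C):
        denom = 2 * a + b + c
        vals.append(2 * a / denom if denom else 0.0)
    return float(np.mean(vals))


@dataclass(frozen=True)
class BinaryCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def binary_counts(y_true, y_pred, positive=SOLUBLE) -> BinaryCounts:
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    return BinaryCounts(
        TP=int(np.sum(t & p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
        TN=int(np.sum(~t & ~p)),
    )


def precision(bc: BinaryCounts) -> float:
    if bc.TP + bc.FP == 0:
        warnings.warn("no positive predictions; precision defined as 0")
        return 0.0
    return bc.TP / (bc.TP + bc.FP)


def recall(bc: BinaryCounts) -> float:
    if bc.TP + bc.FN == 0:
        warnings.warn("no positive instances; recall defined as 0")
        return 0.0
    return bc.TP / (bc.TP + bc.FN)


def f_score(bc: BinaryCounts) -> float:
    p, r = precision(bc), recall(bc)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    TPR: float
    FPR: float
    PPV: float


def roc_prc(scores, truth) -> tuple[list[CurvePoint], list[CurvePoint], float, float]:
    """ROC and PRC by threshold sweep over unique scores; AUCs by trapezoid.

    ``truth`` is boolean (soluble = positive); returns (roc_points,
    prc_points, auROC, auPRC).  ROC gets (0,0)/(1,1) endpoints; auPRC is the
    trapezoid over recall.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the truth vector")
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], truth[order]
    tp = np.cumsum(t)
    fp = np.cumsum(~t)
    # keep the last index of each tied score block
    last = np.nonzero(np.diff(s, append=-np.inf))[0]
    roc_points = [CurvePoint(threshold=np.inf, TPR=0.0, FPR=0.0, PPV=1.0)]
    # PRC anchored at recall 0 with the precision of the top-score block
    first_ppv = tp[last[0]] / (tp[last[0]] + fp[last[0]])
    prc_points = [CurvePoint(threshold=np.inf, TPR=0.0, FPR=0.0, PPV=first_ppv)]
    for i in last:
        tpr = tp[i] / n_pos
        fpr = fp[i] / n_neg
        ppv = tp[i] / (tp[i] + fp[i])
        roc_points.append(CurvePoint(threshold=float(s[i]), TPR=tpr, FPR=fpr, PPV=ppv))
        prc_points.append(CurvePoint(threshold=float(s[i]), TPR=tpr, FPR=fpr, PPV=ppv))
    fprs = np.array([p.FPR for p in roc_points])
    tprs = np.array([p.TPR for p in roc_points])
    auroc = float(np.trapezoid(tprs, fprs))
    recs = np.array([p.TPR for p in prc_points])
    ppvs = np.array([p.PPV for p in prc_points])
    auprc = float(np.trapezoid(ppvs, recs))
    return roc_points, prc_points, auroc, auprc


@dataclass(frozen=True)
class PairedOutcomeCounts:
    N11: int
    N10: int
    N01: int
    N00: int


def yules_q(po: PairedOutcomeCounts) -> float:
    """Yule's Q = (N11*N00 - N01*N10) / (N11*N00 + N01*N10), in [-1, 1]."""
    num = po.N11 * po.N00 - po.N01 * po.N10
    den = po.N11 * po.N00 + po.N01 * po.N10
    if den == 0:
        raise ValueError("Yule's Q undefined: N11*N00 + N01*N10 == 0")
    return num / den


def yules_q_between(correct_a, correct_b) -> float:
    """Yule's Q from the two classifiers' per-instance correctness vectors."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("correctness vectors must have equal length")
    po = PairedOutcomeCounts(
        N11=int(np.sum(a & b)),
        N10=int(np.sum(a & ~b)),
        N01=int(np.sum(~a & b)),
        N00=int(np.sum(~a & ~b)),
    )
    return yules_q(po)


# ---------------------------------------------------------------------------
# protocol


def stratified_partition(instances, m: int, seed: int) -> list[list[int]]:
    """Split instance indices into m parts, per-class balanced within +/-1.

    Per-class shuffle followed by a round-robin deal; deterministic for a
    given seed.  Returns index lists into ``instances``.
    """
    y = np.array([inst.y for inst in instances])
    rng = np.random.default_rng(seed)
    min_class = min(int(np.sum(y == l)) for l in set(y))
    if m > min_class:
        raise ValueError(f"m={m} exceeds smallest class size {min_class}")
    parts: list[list[int]] = [[] for _ in range(m)]
    offset = 0
    for cls in sorted(set(y)):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            parts[(j + offset) % m].append(int(i))
        offset += len(idx)  # rotate the deal so remainders spread over parts
    return [sorted(p) for p in parts]


def _train(method: str, instances, hp: ModelHyperparams, seed: int):
    if method == "flat":
        return clf.train_flat(instances, hp, seed=seed)
    if method == "nest":
        return clf.train_nested(instances, hp, hp, seed=seed)
    if method == "hier":
        return clf.train_hier(instances, hp, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def _predict(method: str, model, X: np.ndarray):
    if method == "ensemble":
        labels, _ = clf.ensemble_predict(model, X)
        return labels
    return clf.predict(model, X)


def _fit_method(method: str, instances, hp: ModelHyperparams, seed: int):
    if method == "ensemble":
        return [_train(m, instances, hp, seed) for m in ("flat", "nest", "hier")]
    return _train(method, instances, hp, seed)


def _soluble_scores(method: str, model, X: np.ndarray) -> np.ndarray:
    if method == "ensemble":
        _, scores = clf.ensemble_predict(model, X)
    else:
        scores = clf.predict_scores(model, X)
    return scores[:, LABELS.index(SOLUBLE)]


def select_hyperparams(
    instances,
    method: str,
    grid=None,
    folds: int = 10,
    seed: int = clf.DEFAULT_SEED,
) -> ModelHyperparams:
    """Pick (C, gamma) by inner stratified k-fold CV accuracy over a grid."""
    if grid is None:
        grid = DEFAULT_GRID
    if len(grid) == 1:
        return grid[0]
    parts = stratified_partition(instances, folds, seed)
    best_hp, best_acc = None, -1.0
    for hp in grid:
        correct = total = 0
        for k, part in enumerate(parts):
            train_idx = [i for j, p in enumerate(parts) if j != k for i in p]
            model = _fit_method(method, [instances[i] for i in train_idx], hp, seed)
            X_val = np.stack([instances[i].x for i in part])
            y_val = np.array([instances[i].y for i in part])
            pred = _predict(method, model, X_val)
            correct += int(np.sum(pred == y_val))
            total += len(part)
        acc = correct / total
        if acc > best_acc:
            best_hp, best_acc = hp, acc
    return best_hp


@dataclass
class EvalReport:
    """Per-repeat metrics with mean +/- SD, plus test outcomes for diversity."""

    method: str
    repeats: list[dict] = field(default_factory=list)
    test_keys: list[list] = field(default_factory=list)
    test_correct: list[list[bool]] = field(default_factory=list)
    roc_curves: list[list[CurvePoint]] = field(default_factory=list)
    prc_curves: list[list[CurvePoint]] = field(default_factory=list)

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = np.array([r[metric] for r in self.repeats])
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, tuple[float, float]]:
        return {k: self.mean_sd(k) for k in self.repeats[0]}

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "repeats": self.repeats,
            "summary": {k: {"mean": m, "sd": s} for k, (m, s) in self.summary().items()},
            "test_keys": [[list(k) for k in keys] for keys in self.test_keys],
            "test_correct": [[bool(c) for c in cs] for cs in self.test_correct],
            "roc_curves": [[asdict(p) for p in c] for c in self.roc_curves],
            "prc_curves": [[asdict(p) for p in c] for c in self.prc_curves],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _test_metrics(method, model, test_instances) -> tuple[dict, np.ndarray]:
    X = np.stack([inst.x for inst in test_instances])
    y = np.array([inst.y for inst in test_instances])
    pred = _predict(method, model, X)
    cc = confusion_counts(y, pred)
    bc = binary_counts(y, pred)
    row = {
        "accuracy": float(np.mean(pred == y)),
        "f1_measure": f1_measure(cc),
        "f_score": f_score(bc),
        "precision": precision(bc),
        "recall": recall(bc),
    }
    return row, pred


def repeated_holdout(
    instances,
    method: str = "flat",
    n_repeats: int = 10,
    m: int = 10,
    seed: int = clf.DEFAULT_SEED,
    grid=None,
    inner_folds: int = 10,
    with_curves: bool = True,
) -> EvalReport:
    """Stratified m-part hold-out with inner CV model selection, repeated.

    Each repeat: one part held out for testing, inner ``inner_folds``-fold CV
    on the rest selects (C, gamma) from ``grid`` (pass a single-element grid
    to skip the search), a final model is fit on all m-1 parts, and test
    metrics are recorded.  Deterministic for a given seed.
    """
    report = EvalReport(method=method)
    for rep in range(n_repeats):
        rep_seed = seed + 1000 * rep
        parts = stratified_partition(instances, m, rep_seed)
        test_idx = parts[rep % m]
        train_idx = [i for j, p in enumerate(parts) if j != rep % m for i in p]
        train = [instances[i] for i in train_idx]
        test = [instances[i] for i in test_idx]
        hp = select_hyperparams(train, method, grid=grid, folds=inner_folds, seed=rep_seed)
        model = _fit_method(method, train, hp, rep_seed)
        row, pred = _test_metrics(method, model, test)
        X = np.stack([inst.x for inst in test])
        y = np.array([inst.y for inst in test])
        if with_curves:
            sol = _soluble_scores(method, model, X)
            roc_pts, prc_pts, auroc, auprc = roc_prc(sol, y == SOLUBLE)
            row["auroc"], row["auprc"] = auroc, auprc
            report.roc_curves.append(roc_pts)
            report.prc_curves.append(prc_pts)
        report.repeats.append(row)
        report.test_keys.append([inst.key for inst in test])
        report.test_correct.append(list(pred == y))
    return report


def per_vector_protocol(
    instances,
    seed: int = clf.DEFAULT_SEED,
    grid=None,
    inner_folds: int = 5,
    folds: int = 5,
) -> dict[str, tuple[float, float]]:
    """Train one three-class flat classifier per vector, 5-fold rotation.

    For each vector, its instances are split into ``folds`` stratified parts;
    each part is tested once with a model fit (after inner CV selection) on
    the others.  Returns vector -> (mean F1, SD over folds).
    """
    vectors = sorted({inst.key[1] for inst in instances})
    out = {}
    for vec in vectors:
        sub = [inst for inst in instances if inst.key[1] == vec]
        parts = stratified_partition(sub, folds, seed)
        f1s = []
        for k in range(folds):
            train_idx = [i for j, p in enumerate(parts) if j != k for i in p]
            train = [sub[i] for i in train_idx]
            test = [sub[i] for i in parts[k]]
            hp = select_hyperparams(train, "flat", grid=grid, folds=inner_folds, seed=seed)
            model = clf.train_flat(train, hp, seed=seed)
            X = np.stack([inst.x for inst in test])
            y = np.array([inst.y for inst in test])
            pred = clf.predict_flat(model, X)
            f1s.append(f1_measure(confusion_counts(y, pred)))
        f1s = np.array(f1s)
        out[vec] = (float(f1s.mean()), float(f1s.std(ddof=1)))
    return out


def paired_t_test(acc_a, acc_b) -> float:
    """Two-sided paired Student's t-test p-value on per-repeat accuracies."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length lists with n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            warnings.warn("identical accuracy lists; p-value degenerate at 1")
            return 1.0
        warnings.warn("zero-variance nonzero difference; p-value degenerate at 0")
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)
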