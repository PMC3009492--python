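"""Three SVM architectures for the three-way expression-efficacy problem.

The label taxonomy is a two-level tree: *soluble* and *insoluble* share the
parent "expressed", while *non_expression* hangs off the root.  Each
architecture uses this structure differently:

``flatSVM``
    Ignores the tree: one RBF-SVM per unordered class pair (1-vs-1), final
    label by majority vote, margin-sum tie-break.
``nestSVM``
    Follows transcription-then-folding: stage 1 predicts expressed vs not on
    the 87 nucleotide-level features; stage 2 predicts soluble vs insoluble
    on the 530 protein-level features, only for stage-1 positives.
``hierSVM``
    Embeds each label as a 4-digit attribute vector encoding the taxonomy
    (digit 4 = "expressed" parent) and reduces hierarchical classification
    to one binary SVM over tensor-product expansions x (x) (a - b), turning
    each 617-vector into a 2468-vector per ordered label pair.

All architectures standardize features with training statistics and use
scikit-learn's RBF-kernel ``SVC``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.svm import SVC

from .features import N_FEATURES, NT_SLICE, PROTEIN_SLICE, StandardTransform

__all__ = [
    "LABELS",
    "SOLUBLE",
    "INSOLUBLE",
    "NON_EXPRESSION",
    "ATTRIBUTE_VECTORS",
    "ModelHyperparams",
    "LabeledInstance",
    "encode_label",
    "expand_instance",
    "FlatModel",
    "NestedModel",
    "HierModel",
    "train_flat",
    "predict_flat",
    "train_nested",
    "predict_nested",
    "train_hier",
    "predict_hier",
    "predict",
    "predict_scores",
    "ensemble_predict",
    "save_model",
    "load_model",
]

SOLUBLE = "soluble"
INSOLUBLE = "insoluble"
NON_EXPRESSION = "non_expression"
LABELS = (SOLUBLE, INSOLUBLE, NON_EXPRESSION)

# 4-digit label attribute vectors: digits 1-3 one-hot the leaf classes,
# digit 4 marks the shared "expressed" parent of soluble and insoluble.
ATTRIBUTE_VECTORS: dict[str, np.ndarray] = {
    SOLUBLE: np.array([1, 0, 0, 1]),
    INSOLUBLE: np.array([0, 1, 0, 1]),
    NON_EXPRESSION: np.array([0, 0, 1, 0]),
}

DEFAULT_SEED = 20100118


@dataclass(frozen=True)
class ModelHyperparams:
    """RBF-SVM hyperparameters (LIBSVM parameterization)."""

    C: float = 8.0
    gamma: float = 2.0**-9

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass(frozen=True)
class LabeledInstance:
    key: tuple[str, str]
    x: np.ndarray
    y: str

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        object.__setattr__(self, "x", x)
        if self.y not in LABELS:
            raise ValueError(f"unknown label {self.y!r}")


def encode_label(y: str) -> np.ndarray:
    """Attribute-vector encoding of a label (see module docstring)."""
    try:
        return ATTRIBUTE_VECTORS[y].copy()
    except KeyError:
        raise ValueError(f"unknown label {y!r}") from None


def expand_instance(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tensor-product expansion x (x) (a - b) -> four 617-blocks (2468 values)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (4,) or b.shape != (4,):
        raise ValueError("attribute vectors must have length 4")
    if np.array_equal(a, b):
        raise ValueError("attribute vectors must differ")
    x = np.asarray(x, dtype=float)
    return np.kron(a - b, x)


def _as_matrix(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def _fit_svc(svm: SVC, X: np.ndarray, y: np.ndarray) -> SVC:
    # sklearn 1.9 deprecation chatter for SVC(probability=True); the Platt
    # pairwise probabilities are part of this model's contract
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        svm.fit(X, y)
    return svm


def _collect(instances) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([inst.x for inst in instances])
    y = np.array([inst.y for inst in instances])
    return X, y


# ---------------------------------------------------------------------------
# flatSVM


_PAIRS = ((SOLUBLE, INSOLUBLE), (SOLUBLE, NON_EXPRESSION), (INSOLUBLE, NON_EXPRESSION))


@dataclass
class FlatModel:
    """1-vs-1 RBF-SVMs with majority voting; margin-sum tie-break."""

    transform: StandardTransform
    pair_svms: dict[tuple[str, str], SVC]
    priors: dict[str, float]
    hp: ModelHyperparams


def train_flat(
    instances, hp: ModelHyperparams = ModelHyperparams(), seed: int = DEFAULT_SEED
) -> FlatModel:
    """Fit one binary RBF-SVM per unordered class pair on pooled-standardized data."""
    X, y = _collect(instances)
    present = set(y)
    missing = [l for l in LABELS if l not in present]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")
    transform, Xs = StandardTransform().fit(X), None
    Xs = transform.apply(X)
    pair_svms = {}
    for pair in _PAIRS:
        mask = np.isin(y, pair)
        svm = SVC(
            kernel="rbf", C=hp.C, gamma=hp.gamma, probability=True, random_state=seed
        )
        _fit_svc(svm, Xs[mask], y[mask])
        pair_svms[pair] = svm
    priors = {l: float(np.mean(y == l)) for l in LABELS}
    return FlatModel(transform=transform, pair_svms=pair_svms, priors=priors, hp=hp)


def _flat_votes_margins(model: FlatModel, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-label vote counts and summed signed decision margins (n x 3 each)."""
    n = Xs.shape[0]
    votes = np.zeros((n, 3))
    margins = np.zeros((n, 3))
    idx = {l: i for i, l in enumerate(LABELS)}
    for (l1, l2), svm in model.pair_svms.items():
        dec = svm.decision_function(Xs)  # >0 favors svm.classes_[1]
        pos_label = svm.classes_[1]
        neg_label = svm.classes_[0]
        pos_wins = dec > 0
        votes[pos_wins, idx[pos_label]] += 1
        votes[~pos_wins, idx[neg_label]] += 1
        margins[:, idx[pos_label]] += dec
        margins[:, idx[neg_label]] -= dec
    return votes, margins


def _argmax_with_tiebreak(
    primary: np.ndarray, *tiebreaks: np.ndarray
) -> np.ndarray:
    """Row-wise argmax over labels; ties resolved by successive criteria."""
    n = primary.shape[0]
    keys = [primary] + list(tiebreaks)
    winner = np.zeros(n, dtype=int)
    for row in range(n):
        best = list(range(primary.shape[1]))
        for key in keys:
            top = max(key[row, j] for j in best)
            best = [j for j in best if key[row, j] == top]
            if len(best) == 1:
                break
        winner[row] = best[0]
    return winner


def predict_flat(model: FlatModel, x: np.ndarray):
    """Majority-vote label; 3-way ties go to the largest summed margin, then prior."""
    X, single = _as_matrix(x)
    Xs = model.transform.apply(X)
    votes, margins = _flat_votes_margins(model, Xs)
    prior_row = np.array([model.priors[l] for l in LABELS])
    priors = np.tile(prior_row, (X.shape[0], 1))
    winner = _argmax_with_tiebreak(votes, margins, priors)
    labels = np.array(LABELS)[winner]
    return labels[0] if single else labels


def _flat_scores(model: FlatModel, Xs: np.ndarray) -> np.ndarray:
    """Pairwise-coupled Platt probabilities, normalized to sum to 1."""
    n = Xs.shape[0]
    scores = np.zeros((n, 3))
    idx = {l: i for i, l in enumerate(LABELS)}
    for pair, svm in model.pair_svms.items():
        proba = svm.predict_proba(Xs)
        for col, label in enumerate(svm.classes_):
            scores[:, idx[label]] += proba[:, col]
    return scores / scores.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# nestSVM


@dataclass
class NestedModel:
    """Expression-then-solubility cascade on disjoint feature blocks."""

    transform: StandardTransform
    stage1: SVC  # expressed vs non_expression, 87 nt features
    stage2: SVC  # soluble vs insoluble, 530 protein features
    hp1: ModelHyperparams
    hp2: ModelHyperparams


def train_nested(
    instances,
    hp1: ModelHyperparams = ModelHyperparams(),
    hp2: ModelHyperparams = ModelHyperparams(),
    seed: int = DEFAULT_SEED,
) -> NestedModel:
    X, y = _collect(instances)
    for label in LABELS:
        if label not in set(y):
            raise ValueError(f"class {label} absent from training data")
    transform = StandardTransform().fit(X)
    Xs = transform.apply(X)
    expressed = y != NON_EXPRESSION
    if expressed.sum() < 2:
        raise ValueError("need at least 2 expressed instances for stage 2")
    stage1 = SVC(kernel="rbf", C=hp1.C, gamma=hp1.gamma, probability=True, random_state=seed)
    _fit_svc(stage1, Xs[:, NT_SLICE], np.where(expressed, "expressed", NON_EXPRESSION))
    stage2 = SVC(kernel="rbf", C=hp2.C, gamma=hp2.gamma, probability=True, random_state=seed)
    _fit_svc(stage2, Xs[expressed][:, PROTEIN_SLICE], y[expressed])
    return NestedModel(transform=transform, stage1=stage1, stage2=stage2, hp1=hp1, hp2=hp2)


def predict_nested(model: NestedModel, x: np.ndarray):
    """Cascade: stage-1 negative -> non_expression, else stage-2 decides."""
    X, single = _as_matrix(x)
    Xs = model.transform.apply(X)
    out = np.empty(X.shape[0], dtype=object)
    s1 = model.stage1.predict(Xs[:, NT_SLICE])
    not_expr = s1 == NON_EXPRESSION
    out[not_expr] = NON_EXPRESSION
    if (~not_expr).any():
        out[~not_expr] = model.stage2.predict(Xs[~not_expr][:, PROTEIN_SLICE])
    labels = out.astype(str)
    return labels[0] if single else labels


def _nested_scores(model: NestedModel, Xs: np.ndarray) -> np.ndarray:
    p1 = model.stage1.predict_proba(Xs[:, NT_SLICE])
    p_expr = p1[:, list(model.stage1.classes_).index("expressed")]
    p2 = model.stage2.predict_proba(Xs[:, PROTEIN_SLICE])
    p_sol = p2[:, list(model.stage2.classes_).index(SOLUBLE)]
    scores = np.column_stack([p_expr * p_sol, p_expr * (1 - p_sol), 1 - p_expr])
    return scores


# ---------------------------------------------------------------------------
# hierSVM


@dataclass
class HierModel:
    """One binary RBF-SVM over 2468-dim tensor-product expansions."""

    transform: StandardTransform
    svm: SVC
    hp: ModelHyperparams


def hier_training_expansions(Xs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expansions and +/-1 targets: per instance, 2 positives and their sign-flips."""
    rows, targets = [], []
    for xi, yi in zip(Xs, y):
        a = ATTRIBUTE_VECTORS[yi]
        for other in LABELS:
            if other == yi:
                continue
            b = ATTRIBUTE_VECTORS[other]
            pos = expand_instance(xi, a, b)
            rows.append(pos)
            targets.append(1)
            rows.append(-pos)  # expand_instance(xi, b, a) == -pos
            targets.append(-1)
    return np.stack(rows), np.array(targets)


def train_hier(
    instances, hp: ModelHyperparams = ModelHyperparams(), seed: int = DEFAULT_SEED
) -> HierModel:
    X, y = _collect(instances)
    transform = StandardTransform().fit(X)
    Xs = transform.apply(X)
    E, t = hier_training_expansions(Xs, y)
    svm = SVC(kernel="rbf", C=hp.C, gamma=hp.gamma, random_state=seed)
    _fit_svc(svm, E, t)
    return HierModel(transform=transform, svm=svm, hp=hp)


def _hier_decisions(model: HierModel, Xs: np.ndarray) -> np.ndarray:
    """Mean decision value per label over its two ordered pairs (n x 3)."""
    n = Xs.shape[0]
    sums = np.zeros((n, 3))
    idx = {l: i for i, l in enumerate(LABELS)}
    sign = 1.0 if model.svm.classes_[1] == 1 else -1.0
    for a_label in LABELS:
        a = ATTRIBUTE_VECTORS[a_label]
        for b_label in LABELS:
            if b_label == a_label:
                continue
            b = ATTRIBUTE_VECTORS[b_label]
            E = Xs[:, None, :] * (a - b)[None, :, None]
            E = E.reshape(n, 4 * Xs.shape[1])
            sums[:, idx[a_label]] += sign * model.svm.decision_function(E)
    return sums / 2.0


def predict_hier(model: HierModel, x: np.ndarray):
    """Argmax of the averaged decision values over the 6 ordered label pairs."""
    X, single = _as_matrix(x)
    Xs = model.transform.apply(X)
    dec = _hier_decisions(model, Xs)
    labels = np.array(LABELS)[np.argmax(dec, axis=1)]
    return labels[0] if single else labels


def _hier_scores(model: HierModel, Xs: np.ndarray) -> np.ndarray:
    dec = _hier_decisions(model, Xs)
    e = np.exp(dec - dec.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# generic dispatch, scores, ensemble, serialization


def predict(model, x: np.ndarray):
    """Predicted label(s) from any trained architecture."""
    if isinstance(model, FlatModel):
        return predict_flat(model, x)
    if isinstance(model, NestedModel):
        return predict_nested(model, x)
    if isinstance(model, HierModel):
        return predict_hier(model, x)
    raise TypeError(f"unknown model type {type(model).__name__}")


def predict_scores(model, x: np.ndarray) -> np.ndarray:
    """Calibrated per-class probabilities in LABELS order (rows sum to 1).

    Accepts any of the three built-in architectures, or a duck-typed member
    exposing its own ``predict_scores(X) -> (n, 3)`` (useful in ensembles).
    """
    X, single = _as_matrix(x)
    if isinstance(model, FlatModel):
        scores = _flat_scores(model, model.transform.apply(X))
    elif isinstance(model, NestedModel):
        scores = _nested_scores(model, model.transform.apply(X))
    elif isinstance(model, HierModel):
        scores = _hier_scores(model, model.transform.apply(X))
    elif hasattr(model, "predict_scores"):
        scores = np.atleast_2d(np.asarray(model.predict_scores(X), dtype=float))
    else:
        raise TypeError(f"unknown model type {type(model).__name__}")
    return scores[0] if single else scores


def ensemble_predict(models, x: np.ndarray):
    """Unweighted mean of member probability vectors; argmax label."""
    if len(models) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    X, single = _as_matrix(x)
    scores = np.mean([predict_scores(m, X) for m in models], axis=0)
    labels = np.array(LABELS)[np.argmax(scores, axis=1)]
    if single:
        return labels[0], scores[0]
    return labels, scores


_FORMAT_VERSION = 1


def save_model(model, path) -> None:
    joblib.dump({"format_version": _FORMAT_VERSION, "model": model}, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != _FORMAT_VERSION:
        warnings.warn(f"model file format {payload.get('format_version')} != {_FORMAT_VERSION}")
    return payload["model"]
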