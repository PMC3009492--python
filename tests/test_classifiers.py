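"""Label encodings, tensor-product expansion, and the three SVM architectures."""

import numpy as np
import pytest

from fxpress import classifiers as clf
from fxpress.classifiers import (
    ATTRIBUTE_VECTORS,
    INSOLUBLE,
    LABELS,
    NON_EXPRESSION,
    SOLUBLE,
    LabeledInstance,
    ModelHyperparams,
    encode_label,
    expand_instance,
)
from fxpress.features import N_FEATURES

from conftest import make_blobs

HP = ModelHyperparams(C=4.0, gamma=2.0**-9)


# -- label attribute vectors and expansion ----------------------------------


@pytest.mark.parametrize(
    "label, vec",
    [
        (SOLUBLE, [1, 0, 0, 1]),
        (INSOLUBLE, [0, 1, 0, 1]),
        (NON_EXPRESSION, [0, 0, 1, 0]),
    ],
)
def test_label_attribute_encoding(label, vec):
    assert encode_label(label).tolist() == vec


def test_encode_rejects_unknown_label():
    with pytest.raises(ValueError):
        encode_label("expressed")


def test_expansion_block_structure():
    x = np.arange(1.0, N_FEATURES + 1)
    e = expand_instance(x, encode_label(SOLUBLE), encode_label(INSOLUBLE))
    blocks = e.reshape(4, N_FEATURES)
    # soluble - insoluble = <1, -1, 0, 0>
    assert np.array_equal(blocks[0], x)
    assert np.array_equal(blocks[1], -x)
    assert np.all(blocks[2] == 0) and np.all(blocks[3] == 0)

    e2 = expand_instance(x, encode_label(SOLUBLE), encode_label(NON_EXPRESSION))
    blocks2 = e2.reshape(4, N_FEATURES)
    # soluble - non_expression = <1, 0, -1, 1>
    assert np.array_equal(blocks2[0], x)
    assert np.all(blocks2[1] == 0)
    assert np.array_equal(blocks2[2], -x)
    assert np.array_equal(blocks2[3], x)


def test_expansion_of_zero_vector_is_zero():
    e = expand_instance(np.zeros(N_FEATURES), encode_label(SOLUBLE), encode_label(INSOLUBLE))
    assert e.shape == (2468,)
    assert np.all(e == 0)


def test_expansion_requires_distinct_attribute_vectors():
    a = encode_label(SOLUBLE)
    with pytest.raises(ValueError):
        expand_instance(np.zeros(N_FEATURES), a, a)


# -- flatSVM ----------------------------------------------------------------


def test_flat_has_three_pairwise_models(blob_instances):
    model = clf.train_flat(blob_instances, HP)
    assert len(model.pair_svms) == 3


def test_flat_requires_all_classes(blob_instances):
    two_class = [i for i in blob_instances if i.y != INSOLUBLE]
    with pytest.raises(ValueError, match="insoluble"):
        clf.train_flat(two_class, HP)


def test_flat_separable_blobs_perfect_on_training(blob_instances):
    model = clf.train_flat(blob_instances, HP)
    X = np.stack([i.x for i in blob_instances])
    y = np.array([i.y for i in blob_instances])
    assert np.mean(clf.predict_flat(model, X) == y) == 1.0


def _tournament_oracle(d_si, d_sn, d_in, priors):
    """Brute-force round-robin: d_xy > 0 means x beats y; margin tie-break."""
    wins = {l: 0 for l in LABELS}
    margin = {l: 0.0 for l in LABELS}
    for (a, b), d in {
        (SOLUBLE, INSOLUBLE): d_si,
        (SOLUBLE, NON_EXPRESSION): d_sn,
        (INSOLUBLE, NON_EXPRESSION): d_in,
    }.items():
        winner = a if d > 0 else b
        wins[winner] += 1
        margin[a] += d
        margin[b] -= d
    ranked = sorted(LABELS, key=lambda l: (wins[l], margin[l], priors[l]), reverse=True)
    return ranked[0]


def test_flat_vote_matches_tournament_oracle_on_random_decisions():
    """500 random pairwise-decision sets, incl. forced cyclic ties."""
    rng = np.random.default_rng(42)
    priors = {SOLUBLE: 0.32, INSOLUBLE: 0.33, NON_EXPRESSION: 0.35}
    idx = {l: i for i, l in enumerate(LABELS)}
    for trial in range(500):
        d_si, d_sn, d_in = rng.normal(size=3)
        if trial % 3 == 0:
            # force a 1-1-1 cycle: s>i, i>n, n>s
            d_si, d_in, d_sn = abs(d_si), abs(d_in), -abs(d_sn)
        votes = np.zeros((1, 3))
        margins = np.zeros((1, 3))
        for (a, b), d in {
            (SOLUBLE, INSOLUBLE): d_si,
            (SOLUBLE, NON_EXPRESSION): d_sn,
            (INSOLUBLE, NON_EXPRESSION): d_in,
        }.items():
            winner = a if d > 0 else b
            votes[0, idx[winner]] += 1
            margins[0, idx[a]] += d
            margins[0, idx[b]] -= d
        prior_row = np.array([[priors[l] for l in LABELS]])
        got = LABELS[clf._argmax_with_tiebreak(votes, margins, prior_row)[0]]
        assert got == _tournament_oracle(d_si, d_sn, d_in, priors)


# -- nestSVM ----------------------------------------------------------------


def test_nested_stage_dimensions(blob_instances):
    model = clf.train_nested(blob_instances, HP, HP)
    assert model.stage1.n_features_in_ == 87
    assert model.stage2.n_features_in_ == 530


def test_nested_stage2_excludes_non_expression(blob_instances):
    model = clf.train_nested(blob_instances, HP, HP)
    n_expressed = sum(1 for i in blob_instances if i.y != NON_EXPRESSION)
    # stage-2 support vectors are drawn from expressed instances only
    assert model.stage2.support_.max() < n_expressed
    assert set(model.stage2.classes_) == {SOLUBLE, INSOLUBLE}


def test_nested_cascade_soundness_fuzz(blob_instances):
    """Never soluble/insoluble when stage-1 is negative, on 10^4 random inputs."""
    model = clf.train_nested(blob_instances, HP, HP)
    rng = np.random.default_rng(7)
    X = rng.normal(0, 4, size=(10_000, N_FEATURES))
    pred = clf.predict_nested(model, X)
    s1 = model.stage1.predict(model.transform.apply(X)[:, :87])
    assert np.all(pred[s1 == NON_EXPRESSION] == NON_EXPRESSION)
    assert np.all(np.isin(pred[s1 == "expressed"], [SOLUBLE, INSOLUBLE]))


def test_nested_perfect_on_planted_two_rule_data():
    """Expression depends on nt features only, solubility on protein only."""
    rng = np.random.default_rng(3)
    instances = []
    for i in range(120):
        x = rng.normal(size=N_FEATURES)
        expressed = x[:87].mean() > 0
        soluble = x[87:].mean() > 0
        if not expressed:
            y = NON_EXPRESSION
        elif soluble:
            y = SOLUBLE
        else:
            y = INSOLUBLE
        x[:87] += 2.0 * (1 if expressed else -1)     # make the rules separable
        x[87:] += 2.0 * (1 if soluble else -1)
        instances.append(LabeledInstance(key=(f"g{i}", "GST"), x=x, y=y))
    model = clf.train_nested(instances, HP, HP)
    X = np.stack([i.x for i in instances])
    y = np.array([i.y for i in instances])
    assert np.mean(clf.predict_nested(model, X) == y) == 1.0


# -- hierSVM ----------------------------------------------------------------


def test_hier_expansion_set_structure(blob_instances):
    X = np.stack([i.x for i in blob_instances[:10]])
    y = np.array([i.y for i in blob_instances[:10]])
    E, t = clf.hier_training_expansions(X, y)
    assert E.shape == (40, 2468)          # 4 expansions per instance
    assert np.sum(t == 1) == np.sum(t == -1) == 20
    # negatives are exact sign-flips of their positives
    assert np.array_equal(E[1::2], -E[0::2])
    assert np.all(t[0::2] == 1) and np.all(t[1::2] == -1)


def test_hier_decision_antisymmetry(blob_instances):
    """f(v) ~ -f(-v) for a kernel machine trained on sign-symmetric data."""
    model = clf.train_hier(blob_instances, HP)
    rng = np.random.default_rng(9)
    V = rng.normal(size=(50, 2468))
    d_pos = model.svm.decision_function(V)
    d_neg = model.svm.decision_function(-V)
    # exact identity for a sign-symmetric dual solution: f(v) + f(-v) = 2b
    b = float(model.svm.intercept_[0])
    assert np.allclose(d_pos + d_neg, 2 * b, atol=1e-6)
    assert abs(b) < 0.05  # the symmetric problem keeps the bias near zero


def test_hier_six_prediction_pairs(blob_instances):
    model = clf.train_hier(blob_instances, HP)
    pairs = [(a, b) for a in LABELS for b in LABELS if a != b]
    assert len(pairs) == 6
    # score of each label averages its two ordered-pair decisions
    x = blob_instances[0].x
    dec = clf._hier_decisions(model, model.transform.apply(x[None, :]))
    assert dec.shape == (1, 3)


@pytest.mark.parametrize("train, predict", [
    (clf.train_flat, clf.predict_flat),
    (lambda inst, hp: clf.train_nested(inst, hp, hp), clf.predict_nested),
    (clf.train_hier, clf.predict_hier),
])
def test_all_architectures_solve_separable_blobs(train, predict):
    train_set = make_blobs(n_per_class=30, seed=21)
    test_set = make_blobs(n_per_class=15, seed=22)
    model = train(train_set, HP)
    X = np.stack([i.x for i in test_set])
    y = np.array([i.y for i in test_set])
    assert np.mean(predict(model, X) == y) >= 0.95


# -- scores, ensemble, serialization ----------------------------------------


def test_scores_sum_to_one_and_agree_with_votes(blob_instances):
    test_set = make_blobs(n_per_class=20, seed=33)
    X = np.stack([i.x for i in test_set])
    for model in [
        clf.train_flat(blob_instances, HP),
        clf.train_nested(blob_instances, HP, HP),
        clf.train_hier(blob_instances, HP),
    ]:
        scores = clf.predict_scores(model, X)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        labels = clf.predict(model, X)
        argmax_labels = np.array(LABELS)[np.argmax(scores, axis=1)]
        assert np.mean(argmax_labels == labels) >= 0.95


def test_ensemble_of_identical_models_equals_single(blob_instances):
    model = clf.train_flat(blob_instances, HP)
    x = blob_instances[0].x
    label, scores = clf.ensemble_predict([model, model], x)
    assert label == clf.predict_flat(model, x)
    assert np.allclose(scores, clf.predict_scores(model, x))


def test_ensemble_cancellation_yields_uniform_scores():
    class Fixed:
        def __init__(self, p):
            self.p = np.asarray(p, dtype=float)

        def predict_scores(self, X):
            return np.tile(self.p, (np.atleast_2d(X).shape[0], 1))

    perfect = Fixed([1.0, 0.0, 0.0])
    anti = Fixed([0.0, 0.5, 0.5])
    _, scores = clf.ensemble_predict([perfect, anti], np.zeros(N_FEATURES))
    assert np.allclose(scores, [0.5, 0.25, 0.25])


def test_model_serialization_round_trip(tmp_path, blob_instances):
    test_set = make_blobs(n_per_class=10, seed=44)
    X = np.stack([i.x for i in test_set])
    for trained in [
        clf.train_flat(blob_instances, HP),
        clf.train_nested(blob_instances, HP, HP),
        clf.train_hier(blob_instances, HP),
    ]:
        path = tmp_path / "model.fxm"
        clf.save_model(trained, path)
        loaded = clf.load_model(path)
        assert np.array_equal(clf.predict(loaded, X), clf.predict(trained, X))
        assert np.allclose(clf.predict_scores(loaded, X), clf.predict_scores(trained, X))
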