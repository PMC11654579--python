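"""Contrastive objective, composite loss, and the seeded training loops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from captox._autodiff import Tensor
from captox.model_core import ModelConfig
from captox.sequence_io import PeptideRecord
from captox.synthetic_data import CorpusSpec, MotifSpec, generate_corpus
from captox.training import (
    ContrastiveConfig,
    TrainConfig,
    batch_contrastive_loss,
    contrastive_pair_loss,
    cosine_distance,
    cross_validate,
    stratified_folds,
    total_loss,
    train,
    training_loss,
)

TINY_MODEL = dict(d=16, n_heads=2, max_len=16, dropout=0.0)


def _pair_at_distance(dist):
    """Two unit 2-vectors with the requested cosine distance."""
    theta = np.arccos(1.0 - dist)
    return np.array([1.0, 0.0]), np.array([np.cos(theta), np.sin(theta)])


# ------------------------------------------------------------------ losses

def test_cosine_distance_anchor_values():
    assert cosine_distance([1, 0], [2, 0]) == pytest.approx(0.0)
    assert cosine_distance([1, 0], [0, 3]) == pytest.approx(1.0)
    assert cosine_distance([1, 0], [-5, 0]) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        cosine_distance([0, 0], [1, 0])


def test_pair_loss_closed_forms():
    z = np.array([1.0, 0.0])
    assert contrastive_pair_loss(z, z, 0) == 0.0
    e2 = np.array([0.0, 1.0])
    assert contrastive_pair_loss(z, e2, 1, d_max=1.5) == pytest.approx(0.0625)
    assert contrastive_pair_loss(z, e2, 0, d_max=1.5) == pytest.approx(0.5)
    # beyond the margin the cross-class term clamps to zero, not negative
    assert contrastive_pair_loss(z, -z, 1, d_max=1.5) == 0.0


def test_pair_loss_rejects_bad_pair_label():
    with pytest.raises(ValueError):
        contrastive_pair_loss([1, 0], [0, 1], 2)


@settings(deadline=None, max_examples=300)
@given(st.integers(0, 2**31 - 1))
def test_pair_loss_nonnegative_zero_iff_satisfied(seed):
    rng = np.random.default_rng(seed)
    z1, z2 = rng.normal(size=2), rng.normal(size=2)
    y = int(rng.integers(2))
    loss = contrastive_pair_loss(z1, z2, y, d_max=1.5)
    assert loss >= 0.0
    d = cosine_distance(z1, z2)
    satisfied = (y == 0 and d == 0.0) or (y == 1 and d >= 1.5)
    assert (loss == 0.0) == satisfied


def test_pair_loss_gradient_directions():
    """Same-class loss grows with D; cross-class loss shrinks with D below
    the margin (so its gradient pushes D up)."""
    eps = 1e-6
    for d in (0.3, 0.9, 1.4):
        lo = contrastive_pair_loss(*_pair_at_distance(d - eps), 0)
        hi = contrastive_pair_loss(*_pair_at_distance(d + eps), 0)
        assert hi > lo
        lo = contrastive_pair_loss(*_pair_at_distance(d - eps), 1)
        hi = contrastive_pair_loss(*_pair_at_distance(d + eps), 1)
        assert hi < lo


def test_batch_loss_cases():
    z = np.array([[1.0, 0.0], [1.0, 0.0]])
    assert batch_contrastive_loss(z, [0, 0]) == 0.0
    z2 = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert batch_contrastive_loss(z2, [0, 1], d_max=1.5) == pytest.approx(0.0625)
    # cosine scale invariance
    assert batch_contrastive_loss(2.0 * z2, [0, 1]) == batch_contrastive_loss(z2, [0, 1])


def test_batch_loss_single_class_warns(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="captox.training"):
        val = batch_contrastive_loss(np.array([[1.0, 0.0], [0.0, 1.0]]), [1, 1])
    assert val == pytest.approx(0.5)
    assert any("single-class" in r.message for r in caplog.records)


def test_total_loss_degenerate_weight_is_bce():
    probs, labels = [0.9, 0.2], [1, 0]
    z = np.array([[1.0, 0.0], [0.0, 1.0]])
    bce = -np.mean([np.log(0.9), np.log(0.8)])
    assert total_loss(probs, labels, z, ContrastiveConfig(lam=0.0)) == pytest.approx(bce)
    full = total_loss(probs, labels, z, ContrastiveConfig(lam=1.0))
    assert full >= bce and full >= batch_contrastive_loss(z, labels)


def test_total_loss_zero_at_perfection():
    z = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
    val = total_loss([1.0, 1.0, 0.0], [1, 1, 0], z, ContrastiveConfig(d_max=1.5))
    assert val == pytest.approx(0.0, abs=1e-9)


def test_tensor_loss_matches_reference_formulas():
    rng = np.random.default_rng(5)
    n, d = 6, 4
    logits = rng.normal(size=(n, 2))
    z = rng.normal(size=(n, d))
    labels = rng.integers(0, 2, n)
    cc = ContrastiveConfig(d_max=1.5, lam=0.7)
    loss, bce, con = training_loss(Tensor(logits), Tensor(z), labels, cc)
    probs = np.exp(logits[:, 1]) / np.exp(logits).sum(axis=1)
    want = total_loss(probs, labels, z, cc)
    assert float(loss.data) == pytest.approx(want, abs=1e-8)
    assert con == pytest.approx(batch_contrastive_loss(z, labels, 1.5), abs=1e-8)


# ----------------------------------------------------------------- training

def _toy_corpus(n_pos=12, n_neg=24, seed=0):
    spec = CorpusSpec(
        n_pos=n_pos, n_neg=n_neg, min_len=6, max_len=14, seed=seed,
        motifs=[MotifSpec("WWKK", "head", 1.0, 0.0)],
    )
    return generate_corpus(spec)


def test_train_requires_both_classes():
    recs = [PeptideRecord(f"p{i}", "ACDEF", "toxic") for i in range(4)]
    with pytest.raises(ValueError):
        train(recs, ModelConfig(**TINY_MODEL), TrainConfig(epochs=1))


def test_train_deterministic_given_seed():
    recs = _toy_corpus()
    out = []
    for _ in range(2):
        res = train(
            recs,
            ModelConfig(seed=3, **TINY_MODEL),
            TrainConfig(epochs=2, batch_size=8, seed=3),
        )
        out.append(res.model.predict_proba(recs))
    assert np.array_equal(out[0], out[1])
    assert res.history[0].keys() >= {"bce", "contrastive", "total"}


def test_training_loss_trend_on_separable_data():
    recs = _toy_corpus(16, 32, seed=1)
    res = train(
        recs,
        ModelConfig(seed=1, **TINY_MODEL),
        TrainConfig(epochs=5, batch_size=16, seed=1, lr_schedule="constant"),
    )
    totals = [h["total"] for h in res.history]
    assert all(b <= a + 1e-6 for a, b in zip(totals, totals[1:]))


def test_contrastive_term_raises_sensitivity_on_imbalanced_data():
    """On a 1:9 corpus, adding the contrastive term raises mean held-out SN
    relative to cross-entropy-only training (directional, desk scale)."""
    from captox.workflows import contrastive_ablation_study

    out = contrastive_ablation_study(seed=4)
    assert out["mean_sn"][1.0] > out["mean_sn"][0.0]


# ---------------------------------------------------------- cross-validation

def test_stratified_folds_balanced_toy():
    recs = [
        PeptideRecord("a", "ACDEF", "toxic"),
        PeptideRecord("b", "CDEFG", "toxic"),
        PeptideRecord("c", "DEFGH", "non_toxic"),
        PeptideRecord("d", "EFGHI", "non_toxic"),
    ]
    folds = stratified_folds(recs, 2, seed=0)
    assert sorted(len(f) for f in folds) == [2, 2]
    for f in folds:
        labels = [recs[i].label for i in f]
        assert sorted(labels) == ["non_toxic", "toxic"]


def test_folds_stable_under_reordering():
    recs = _toy_corpus(6, 12, seed=2)
    folds_a = stratified_folds(recs, 3, seed=4)
    shuffled = list(reversed(recs))
    folds_b = stratified_folds(shuffled, 3, seed=4)
    ids_a = [sorted(recs[i].id for i in f) for f in folds_a]
    ids_b = [sorted(shuffled[i].id for i in f) for f in folds_b]
    assert ids_a == ids_b


def test_folds_reject_small_class():
    recs = [PeptideRecord("a", "ACDEF", "toxic")] + [
        PeptideRecord(f"n{i}", "CDEFG", "non_toxic") for i in range(5)
    ]
    with pytest.raises(ValueError):
        stratified_folds(recs, 2, seed=0)


def test_cross_validate_reports_mean_of_folds():
    recs = _toy_corpus(10, 20, seed=6)
    result = cross_validate(
        recs, 2,
        ModelConfig(seed=6, **TINY_MODEL),
        TrainConfig(epochs=2, batch_size=16, seed=6),
    )
    assert len(result.fold_reports) == 2
    assert result.mean["bacc"] == pytest.approx(
        np.mean([r.bacc for r in result.fold_reports])
    )
    assert result.pooled.auc is not None
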