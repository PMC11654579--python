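"""Encoder operators against naive loop oracles, mask contracts, pooling."""

import numpy as np
import pytest

from captox.model_core import (
    CAPTPModel,
    ModelConfig,
    conv_modulation,
    multi_head_attention,
    pool,
)
from captox.sequence_io import PeptideRecord, encode_batch


from _oracles import attention_oracle, conv_modulation_oracle  # noqa: E402


# ----------------------------------------------------------- conv modulation

def test_conv_modulation_k1_reduces_to_gating():
    x = np.array([[2.0, -1.0]])
    z = conv_modulation(x, np.eye(2), np.eye(2), np.ones((1, 2)))
    assert np.allclose(z, [[4.0, 1.0]])


def test_conv_modulation_hand_example():
    """d=1, L=3, unit weights, kernel [1,1,1]: A=[3,6,5], Z=[3,12,15]."""
    x = np.array([[1.0], [2.0], [3.0]])
    z = conv_modulation(x, np.ones((1, 1)), np.ones((1, 1)), np.ones((3, 1)))
    assert np.allclose(z.ravel(), [3.0, 12.0, 15.0])


def test_conv_modulation_zero_input():
    z = conv_modulation(np.zeros((4, 3)), np.eye(3), np.eye(3), np.ones((3, 3)))
    assert np.allclose(z, 0.0)


@pytest.mark.parametrize("seed", range(20))
def test_conv_modulation_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    L, d = int(rng.integers(1, 11)), int(rng.integers(1, 9))
    k = int(rng.choice([1, 3, 5]))
    x = rng.normal(size=(L, d))
    w1, w2 = rng.normal(size=(d, d)), rng.normal(size=(d, d))
    kernel = rng.normal(size=(k, d))
    got = conv_modulation(x, w1, w2, kernel)
    want = conv_modulation_oracle(x, w1, w2, kernel)
    assert np.allclose(got, want, atol=1e-6)


def test_conv_modulation_locality_k3():
    """With k=3, perturbing position p changes the gate A only at |q-p|<=1."""
    rng = np.random.default_rng(0)
    L, d = 8, 4
    x = rng.normal(size=(L, d))
    w1, kernel = rng.normal(size=(d, d)), rng.normal(size=(3, d))
    # recover the gate A as Z / V with V = X (w2 = I, rows nonzero a.s.)
    base = conv_modulation(x, w1, np.eye(d), kernel) / (x @ np.eye(d))
    p = 4
    x2 = x.copy()
    x2[p] += 1.0
    pert = conv_modulation(x2, w1, np.eye(d), kernel) / (x2 @ np.eye(d))
    for q in range(L):
        if abs(q - p) > 1:
            assert np.allclose(base[q], pert[q], atol=1e-9)
    assert not np.allclose(base[p], pert[p])


# --------------------------------------------------------------- attention

def test_attention_uniform_over_identical_keys():
    x = np.array([[1.0], [1.0]])
    eye = np.eye(1)
    out = multi_head_attention(x, eye, eye, eye, eye, n_heads=1)
    assert np.allclose(out, [[1.0], [1.0]])


def test_attention_zero_input_gives_zeros():
    rng = np.random.default_rng(1)
    d = 4
    ws = [rng.normal(size=(d, d)) for _ in range(4)]
    out = multi_head_attention(np.zeros((5, d)), *ws, n_heads=2)
    assert np.allclose(out, 0.0)


@pytest.mark.parametrize("seed", range(20))
def test_attention_matches_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    n_heads = int(rng.choice([1, 2, 4]))
    d = n_heads * int(rng.integers(1, 4))
    L = int(rng.integers(1, 11))
    x = rng.normal(size=(L, d))
    ws = [rng.normal(size=(d, d)) for _ in range(4)]
    scaling = bool(rng.integers(2))
    got = multi_head_attention(x, *ws, n_heads=n_heads, scaling=scaling)
    want = attention_oracle(x, *ws, n_heads=n_heads, scaling=scaling)
    assert np.allclose(got, want, atol=1e-6)


def test_attention_softmax_rows_sum_to_one_over_unmasked():
    from captox._autodiff import Tensor
    from captox.model_core import masked_softmax

    rng = np.random.default_rng(2)
    logits = Tensor(rng.normal(size=(2, 1, 4, 4)))
    mask = np.array([[True, True, True, False], [True, True, False, False]])
    s = masked_softmax(logits, mask[:, None, None, :]).data
    assert np.allclose(s.sum(axis=-1), 1.0, atol=1e-6)
    assert np.all(s[0, :, :, 3] < 1e-6)
    assert np.all(s[1, :, :, 2:] < 1e-6)


# ------------------------------------------------------------------ pooling

def test_pool_examples():
    f = np.array([[1.0, 3.0], [2.0, 0.0]])
    m = np.array([True, True])
    assert np.allclose(pool(f, m, "max"), [2.0, 3.0])
    assert np.allclose(pool(f, m, "min"), [1.0, 0.0])
    assert np.allclose(pool(f, m, "mean"), [1.5, 1.5])
    one = np.array([True, False])
    assert np.allclose(pool(f, one, "mean"), f[0])


def test_pool_ignores_padding_content():
    rng = np.random.default_rng(3)
    f = rng.normal(size=(5, 3))
    m = np.array([True, True, True, False, False])
    g = f.copy()
    g[3:] = 99.0
    for method in ("max", "min", "mean"):
        assert np.allclose(pool(f, m, method), pool(g, m, method))
    w = rng.normal(size=3)
    assert np.allclose(pool(f, m, "attention", w), pool(g, m, "attention", w))


def test_pool_rejects_empty_mask():
    with pytest.raises(ValueError):
        pool(np.ones((2, 2)), np.array([False, False]), "max")


# ------------------------------------------------------------- whole model

def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(d=10, n_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(k=2)
    with pytest.raises(ValueError):
        ModelConfig(pooling="sum")


def test_embed_additivity_and_position_decomposition():
    cfg = ModelConfig(d=8, n_heads=2, max_len=6, dropout=0.0, seed=0)
    model = CAPTPModel(cfg)
    batch = encode_batch([PeptideRecord("x", "AA")], cfg.max_len)
    x = model.embed(batch).data[0]
    # identical tokens at different positions differ by PosEmb rows only
    pos_diff = model.pos_emb.data[0] - model.pos_emb.data[1]
    assert np.allclose(x[0] - x[1], pos_diff)
    model.token_emb.data[:] = 0.0
    model.pos_emb.data[:] = 0.0
    assert np.allclose(model.embed(batch).data, 0.0)


def test_embed_rejects_out_of_vocab():
    cfg = ModelConfig(d=8, n_heads=2, max_len=4, seed=0)
    model = CAPTPModel(cfg)
    batch = encode_batch([PeptideRecord("x", "AC")], cfg.max_len)
    batch.tokens[0, 0] = 30
    with pytest.raises(ValueError):
        model.embed(batch)


def test_untrained_zeroed_head_predicts_half():
    cfg = ModelConfig(d=8, n_heads=2, max_len=10, dropout=0.0, seed=1)
    model = CAPTPModel(cfg)
    model.head.w.data[:] = 0.0
    model.head.b.data[:] = 0.0
    probs = model.predict_proba(["ACDEF", "KLMNP"])
    assert np.allclose(probs, 0.5)


def test_probabilities_complement_to_one():
    from captox.model_core import softmax_rows

    cfg = ModelConfig(d=8, n_heads=2, max_len=10, dropout=0.0, seed=1)
    model = CAPTPModel(cfg)
    batch = model._encode(["ACDEF", "KLMNP", "WWWW"])
    logits, _ = model.forward(batch)
    p = softmax_rows(logits).data
    assert np.allclose(p.sum(axis=1), 1.0)


def test_batch_permutation_equivariance():
    cfg = ModelConfig(d=8, n_heads=2, max_len=12, dropout=0.0, seed=2)
    model = CAPTPModel(cfg)
    seqs = ["ACDEFG", "KLM", "WYVTSACD"]
    p = model.predict_proba(seqs)
    q = model.predict_proba(seqs[::-1])
    assert np.allclose(p, q[::-1])


def test_padding_content_never_leaks():
    cfg = ModelConfig(d=8, n_heads=2, max_len=10, dropout=0.0, seed=3)
    model = CAPTPModel(cfg)
    batch = model._encode(["ACDEF"])
    logits1, _ = model.forward(batch)
    batch.tokens[0, 7:] = 5  # garbage under the mask
    logits2, _ = model.forward(batch)
    assert np.allclose(logits1.data, logits2.data)


def test_forward_finite_on_random_batches():
    cfg = ModelConfig(d=8, n_heads=2, max_len=10, dropout=0.0, seed=4)
    model = CAPTPModel(cfg)
    rng = np.random.default_rng(0)
    from captox.sequence_io import AMINO_ACIDS

    for _ in range(50):
        seqs = [
            "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 11)))
            for _ in range(4)
        ]
        logits, pooled = model.forward(model._encode(seqs))
        assert np.isfinite(logits.data).all() and np.isfinite(pooled.data).all()


def test_zeroed_residual_branches_leave_normalised_input():
    """With every sublayer's output weights zeroed, each block reduces to
    two successive layer norms of its input."""
    cfg = ModelConfig(d=8, n_heads=2, max_len=10, dropout=0.0, seed=7)
    model = CAPTPModel(cfg)
    for blk in model.blocks:
        for name in ("w1", "w2", "kernel", "wq", "wk", "wv", "wo"):
            if hasattr(blk, name):
                getattr(blk, name).data[:] = 0.0
        blk.ffn.fc2.w.data[:] = 0.0
        blk.ffn.fc2.b.data[:] = 0.0
    batch = model._encode(["ACDEF"])
    got = model.encoder_forward(batch).data[0, :5]

    def ln(x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / np.sqrt(var + 1e-5)

    expected = model.embed(batch).data[0, :5]
    for _ in model.blocks:
        expected = ln(ln(expected))
    assert np.allclose(got, expected, atol=1e-9)


def test_invalid_sequence_error_names_record():
    cfg = ModelConfig(d=8, n_heads=2, seed=0)
    model = CAPTPModel(cfg)
    with pytest.raises(ValueError, match="badseq"):
        model.predict_proba([PeptideRecord("badseq", "ACXJ")])


def test_checkpoint_round_trip(tmp_path):
    cfg = ModelConfig(d=8, n_heads=2, max_len=10, dropout=0.0, seed=5, pooling="mean")
    model = CAPTPModel(cfg)
    p1 = model.predict_proba(["ACDEF", "KLMNP"])
    path = tmp_path / "model.ckpt"
    model.save(path)
    loaded = CAPTPModel.load(path)
    assert loaded.config == cfg
    assert np.allclose(loaded.predict_proba(["ACDEF", "KLMNP"]), p1)


def test_cls_pooling_uses_cls_row():
    cfg = ModelConfig(d=8, n_heads=2, max_len=10, dropout=0.0, seed=6, pooling="cls")
    model = CAPTPModel(cfg)
    batch = model._encode(["ACDEF"])
    assert batch.tokens[0, 0] == 21  # CLS prepended automatically
    features = model.encoder_forward(batch)
    pooled = model.forward(batch)[1]
    assert np.allclose(pooled.data[0], features.data[0, 0])
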