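"""Naive loop oracles, independent of the package's vectorised code paths."""

import numpy as np


def conv_modulation_oracle(x, w1, w2, kernel):
    """Triple loop over position, channel, kernel offset."""
    L, d = x.shape
    k = kernel.shape[0]
    h = k // 2
    u = x @ w1
    a = np.zeros((L, d))
    for p in range(L):
        for c in range(d):
            for j in range(k):
                q = p + j - h
                if 0 <= q < L:
                    a[p, c] += kernel[j, c] * u[q, c]
    return a * (x @ w2)


def attention_oracle(x, wq, wk, wv, wo, n_heads, scaling):
    """Two-loop softmax attention per head."""
    L, d = x.shape
    dk = d // n_heads
    out = np.zeros((L, d))
    for head in range(n_heads):
        cols = slice(head * dk, (head + 1) * dk)
        q, k, v = x @ wq[:, cols], x @ wk[:, cols], x @ wv[:, cols]
        scale = 1.0 / np.sqrt(dk) if scaling else 1.0
        for i in range(L):
            logits = np.array([q[i] @ k[j] * scale for j in range(L)])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            out[i, cols] = sum(w[j] * v[j] for j in range(L))
    return out @ wo


def ism_naive(model, seq, amino_acids):
    """One-at-a-time in-silico mutagenesis, no batching."""
    p_wt = model.predict_proba([seq])[0]
    scores = np.zeros((len(seq), 20))
    for p, ref in enumerate(seq):
        for a, aa in enumerate(amino_acids):
            if aa == ref:
                continue
            mutant = seq[:p] + aa + seq[p + 1 :]
            scores[p, a] = abs(model.predict_proba([mutant])[0] - p_wt)
    return scores
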