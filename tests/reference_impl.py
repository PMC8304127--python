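"""Independent scalar/brute-force reference implementations used as oracles.

Everything here is written with explicit Python loops (or plain dict
counting) and stays independent of the vectorized code paths it checks.
"""

from __future__ import annotations

import math


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def scalar_lstm_gates(x, h_prev, c_prev, params):
    """One LSTM step with scalar loops; returns (f, i, o, c_tilde, c, h) lists."""
    D = len(x)
    H = len(h_prev)

    def affine(W, V, b, j):
        s = b[j]
        for d in range(D):
            s += x[d] * W[d][j]
        for k in range(H):
            s += h_prev[k] * V[k][j]
        return s

    f = [_sigmoid(affine(params.W["f"], params.V["f"], params.b["f"], j)) for j in range(H)]
    i = [_sigmoid(affine(params.W["i"], params.V["i"], params.b["i"], j)) for j in range(H)]
    o = [_sigmoid(affine(params.W["o"], params.V["o"], params.b["o"], j)) for j in range(H)]
    ct = [math.tanh(affine(params.W["c"], params.V["c"], params.b["c"], j)) for j in range(H)]
    c = [f[j] * c_prev[j] + i[j] * ct[j] for j in range(H)]
    h = [o[j] * math.tanh(c[j]) for j in range(H)]
    return f, i, o, ct, c, h


def scalar_bilstm(embedded, fwd, bwd):
    """Scalar-loop bidirectional LSTM; returns N x 2H hidden states as lists."""
    n = len(embedded)
    H = len(fwd.b["f"])
    out = [[0.0] * (2 * H) for _ in range(n)]
    h = [0.0] * H
    c = [0.0] * H
    for k in range(n):
        *_, c, h = scalar_lstm_gates(embedded[k], h, c, fwd)
        out[k][:H] = h
    h = [0.0] * H
    c = [0.0] * H
    for k in range(n - 1, -1, -1):
        *_, c, h = scalar_lstm_gates(embedded[k], h, c, bwd)
        out[k][H:] = h
    return out


def scalar_attention(hidden_states, W, b, u):
    """Additive attention with scalar loops; returns (weights, sentence vector)."""
    n = len(hidden_states)
    A = len(b)
    scores = []
    for hs in hidden_states:
        s = 0.0
        for a in range(A):
            z = b[a]
            for d in range(len(hs)):
                z += hs[d] * W[d][a]
            s += u[a] * math.tanh(z)
        scores.append(s)
    mx = max(scores)
    e = [math.exp(s - mx) for s in scores]
    tot = sum(e)
    alpha = [v / tot for v in e]
    dim = len(hidden_states[0])
    sent = [sum(alpha[k] * hidden_states[k][d] for k in range(n)) for d in range(dim)]
    return alpha, sent


def brute_tfidf(token_lists, orders=(2, 3), min_df=1):
    """Brute-force TF-IDF by exhaustive n-gram enumeration.

    Returns (sorted n-gram list, dense matrix as list of lists) with
    tf = raw count and idf = log((1+N)/(1+df)).
    """
    n_docs = len(token_lists)
    per_doc = []
    for toks in token_lists:
        counts: dict[str, int] = {}
        for n in orders:
            for i in range(len(toks) - n + 1):
                g = " ".join(toks[i : i + n])
                counts[g] = counts.get(g, 0) + 1
        per_doc.append(counts)
    df: dict[str, int] = {}
    for counts in per_doc:
        for g in counts:
            df[g] = df.get(g, 0) + 1
    vocab = sorted(g for g, d in df.items() if d >= min_df)
    matrix = []
    for counts in per_doc:
        row = []
        for g in vocab:
            idf = math.log((1 + n_docs) / (1 + df[g]))
            row.append(counts.get(g, 0) * idf)
        matrix.append(row)
    return vocab, matrix
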