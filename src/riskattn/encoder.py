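"""Recurrent attention encoder: embedding sequence -> BiLSTM -> additive attention.

The gate equations are the classic LSTM recurrence

    f_k = sigmoid(W_f x_k + V_f h_{k-1} + b_f)
    i_k = sigmoid(W_i x_k + V_i h_{k-1} + b_i)
    o_k = sigmoid(W_o x_k + V_o h_{k-1} + b_o)
    c~_k = tanh(W_c x_k + V_c h_{k-1} + b_c)
    c_k = f_k * c_{k-1} + i_k * c~_k
    h_k = o_k * tanh(c_k)

run forward and backward over the token sequence with zero initial states;
the two directional hidden states are concatenated per position, so with H
units per direction each position carries a 2H vector. Additive
(Bahdanau-style) self-attention then scores each position through a learned
tanh projection and context vector, normalizes the scores with a masked
softmax, and returns the attention-weighted sum as the sentence vector.

This module is the single-sequence, forward-only reference path; the
trainable batched model in :mod:`riskattn.model` computes the identical
function through the autodiff engine (an equivalence the tests enforce).
"""

from __future__ import annotations

import html as _html
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Post

__all__ = [
    "LSTMParams",
    "AttentionParams",
    "EncoderState",
    "AttentionOutput",
    "lstm_step",
    "bilstm_encode",
    "self_attention",
    "export_attention",
    "read_attention",
]

GATES = ("f", "i", "o", "c")


@dataclass
class LSTMParams:
    """Per-gate input weights W (D x H), recurrent weights V (H x H), biases b (H,)."""

    W: dict[str, np.ndarray]
    V: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    def __post_init__(self):
        D, H = self.W["f"].shape
        for g in GATES:
            if self.W[g].shape != (D, H) or self.V[g].shape != (H, H) or self.b[g].shape != (H,):
                raise ValueError(f"inconsistent parameter shapes for gate {g!r}")

    @property
    def input_dim(self) -> int:
        return self.W["f"].shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W["f"].shape[1]

    @classmethod
    def random(cls, input_dim: int, hidden_dim: int, rng: np.random.Generator) -> "LSTMParams":
        """Uniform(-1/sqrt(H), 1/sqrt(H)) initialization, one draw per gate."""
        k = 1.0 / math.sqrt(hidden_dim)
        return cls(
            W={g: rng.uniform(-k, k, size=(input_dim, hidden_dim)) for g in GATES},
            V={g: rng.uniform(-k, k, size=(hidden_dim, hidden_dim)) for g in GATES},
            b={g: rng.uniform(-k, k, size=hidden_dim) for g in GATES},
        )


@dataclass
class AttentionParams:
    """Additive attention: score_k = u . tanh(W h_k + b)."""

    W: np.ndarray  # (2H, A)
    b: np.ndarray  # (A,)
    u: np.ndarray  # (A,) trainable context vector

    @classmethod
    def random(cls, state_dim: int, attn_dim: int, rng: np.random.Generator) -> "AttentionParams":
        k = 1.0 / math.sqrt(attn_dim)
        return cls(
            W=rng.uniform(-k, k, size=(state_dim, attn_dim)),
            b=rng.uniform(-k, k, size=attn_dim),
            u=rng.uniform(-k, k, size=attn_dim),
        )


@dataclass
class EncoderState:
    """Per-position BiLSTM hidden states (N x 2H) and the validity mask."""

    hidden_states: np.ndarray
    mask: np.ndarray  # (N,) bool; False positions carry zero vectors


@dataclass
class AttentionOutput:
    """Attention weights (N,) summing to 1 over unmasked positions, and the sentence vector (2H,)."""

    weights: np.ndarray
    sentence_vector: np.ndarray


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm_step(
    x_k: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; returns (h_k, c_k)."""
    if x_k.shape != (params.input_dim,) or h_prev.shape != (params.hidden_dim,) or c_prev.shape != (
        params.hidden_dim,
    ):
        raise ValueError(
            f"shape mismatch: x {x_k.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"vs params (D={params.input_dim}, H={params.hidden_dim})"
        )
    f = _sigmoid(x_k @ params.W["f"] + h_prev @ params.V["f"] + params.b["f"])
    i = _sigmoid(x_k @ params.W["i"] + h_prev @ params.V["i"] + params.b["i"])
    o = _sigmoid(x_k @ params.W["o"] + h_prev @ params.V["o"] + params.b["o"])
    c_tilde = np.tanh(x_k @ params.W["c"] + h_prev @ params.V["c"] + params.b["c"])
    c_k = f * c_prev + i * c_tilde
    h_k = o * np.tanh(c_k)
    return h_k, c_k


def bilstm_encode(
    embedded: np.ndarray, mask: np.ndarray, fwd: LSTMParams, bwd: LSTMParams
) -> EncoderState:
    """Run both directions over the unmasked prefix; concatenate per position.

    Initial hidden and cell states are zero in both directions. Masked (pad)
    positions are excluded from both recurrences and carry zero state
    vectors, so padding cannot leak into the representation.
    """
    embedded = np.asarray(embedded, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    n = embedded.shape[0]
    if n == 0 or not mask.any():
        raise ValueError("cannot encode an all-masked (empty) sequence")
    valid = np.flatnonzero(mask)
    H = fwd.hidden_dim
    out = np.zeros((n, 2 * H), dtype=np.float64)

    h = np.zeros(H)
    c = np.zeros(H)
    for k in valid:
        h, c = lstm_step(embedded[k], h, c, fwd)
        out[k, :H] = h

    h = np.zeros(bwd.hidden_dim)
    c = np.zeros(bwd.hidden_dim)
    for k in valid[::-1]:
        h, c = lstm_step(embedded[k], h, c, bwd)
        out[k, H:] = h

    return EncoderState(hidden_states=out, mask=mask)


def self_attention(states: EncoderState, params: AttentionParams) -> AttentionOutput:
    """Additive self-attention over the unmasked positions.

    score_k = u . tanh(W h_k + b); weights = softmax(score) restricted to
    unmasked positions (max subtracted before exponentiation); the sentence
    vector is the weights-weighted sum of hidden states, hence a convex
    combination of them.
    """
    if not states.mask.any():
        raise ValueError("attention requires at least one unmasked position")
    hs = states.hidden_states
    scores = np.tanh(hs @ params.W + params.b) @ params.u
    scores = np.where(states.mask, scores, -np.inf)
    scores = scores - scores.max()
    e = np.where(states.mask, np.exp(scores), 0.0)
    alpha = e / e.sum()
    sentence = alpha @ hs
    return AttentionOutput(weights=alpha, sentence_vector=sentence)


# ---------------------------------------------------------------------------
# attention export (token-weight table + heat-map rendering)
# ---------------------------------------------------------------------------


def export_attention(post: Post, output: AttentionOutput, path) -> None:
    """Write per-token attention weights as TSV and an HTML heat map.

    The TSV has one (token, weight) row per token. The companion
    ``<path>.html`` renders each token on a red background whose opacity is
    the weight rescaled by the maximum weight, so the most-attended token is
    deepest.
    """
    weights = output.weights[: len(post.tokens)]
    if len(weights) != len(post.tokens):
        raise ValueError(
            f"post {post.post_id!r}: {len(post.tokens)} tokens but {len(weights)} attention weights"
        )
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("token\tweight\n")
        for tok, w in zip(post.tokens, weights):
            fh.write(f"{tok}\t{w:.10g}\n")

    top = weights.max() if weights.size else 1.0
    spans = "".join(
        f'<span style="background: rgba(220, 38, 38, {w / top:.3f}); '
        f'padding: 2px 3px; margin: 1px; border-radius: 3px;">{_html.escape(tok)}</span>\n'
        for tok, w in zip(post.tokens, weights)
    )
    html_doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>attention: {_html.escape(post.post_id)}</title></head>"
        "<body style='font-family: sans-serif; line-height: 2.0; max-width: 48em;'>"
        f"<h3>post {_html.escape(post.post_id)} (risk {post.risk_label})</h3><p>{spans}</p>"
        "</body></html>"
    )
    path.with_suffix(path.suffix + ".html").write_text(html_doc, encoding="utf-8")


def read_attention(path) -> tuple[list[str], np.ndarray]:
    """Parse an exported attention TSV back into (tokens, weights)."""
    tokens: list[str] = []
    weights: list[float] = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if header.rstrip("\n") != "token\tweight":
            raise ValueError(f"{path}: not an attention TSV")
        for line in fh:
            tok, w = line.rstrip("\n").split("\t")
            tokens.append(tok)
            weights.append(float(w))
    return tokens, np.array(weights)
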