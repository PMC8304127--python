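"""Fusion classifier: sentence vector + external features -> MLP -> softmax,
trained under a distribution-weighted, L2-regularized cross-entropy.

The loss for a batch of size B with M classes is

    L = (1/B) * sum_i  -gamma_{c(i)} * log p_i(c(i))  +  lambda * ||theta||^2

where c(i) is the true class, gamma is a vector of per-class distribution
weights — trainable, initialized from inverse class frequency so that
classes with more training data get smaller weights — and ||theta||^2 sums
the squares of all weight matrices (embeddings, biases and gamma itself are
excluded by default). gamma is stored as log-weights and exponentiated, so
gradient steps can never drive a class weight negative.

:class:`FusionModel` is the end-to-end trainable network (embedding ->
BiLSTM -> additive attention -> feature fusion -> MLP -> softmax) built on
the in-package autodiff engine; the plain-numpy functions here
(:func:`classify`, :func:`distribution_loss`) are the forward-only
reference path for the classification head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_rows, masked_softmax
from .encoder import GATES, AttentionParams, LSTMParams

__all__ = [
    "ClassifierParams",
    "LossConfig",
    "FusionModel",
    "classify",
    "distribution_loss",
    "init_distribution_weights",
]


# ---------------------------------------------------------------------------
# classification head (plain-numpy reference)
# ---------------------------------------------------------------------------


@dataclass
class ClassifierParams:
    """One-hidden-layer MLP: input -> tanh hidden -> M logits."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @classmethod
    def random(
        cls, input_dim: int, n_classes: int, rng: np.random.Generator, hidden_dim: int | None = None
    ) -> "ClassifierParams":
        hidden_dim = hidden_dim or max(n_classes, input_dim // 2)
        k1 = 1.0 / math.sqrt(input_dim)
        k2 = 1.0 / math.sqrt(hidden_dim)
        return cls(
            W1=rng.uniform(-k1, k1, size=(input_dim, hidden_dim)),
            b1=rng.uniform(-k1, k1, size=hidden_dim),
            W2=rng.uniform(-k2, k2, size=(hidden_dim, n_classes)),
            b2=rng.uniform(-k2, k2, size=n_classes),
        )


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def classify(sentence_vector: np.ndarray, features: np.ndarray, params: ClassifierParams) -> np.ndarray:
    """Class probabilities for one post: softmax(MLP([sentence | features])).

    Probabilities are strictly positive and sum to 1; the predicted class is
    the argmax (lowest index on ties).
    """
    fused = np.concatenate([np.asarray(sentence_vector, float), np.asarray(features, float)])
    if fused.shape[0] != params.W1.shape[0]:
        raise ValueError(
            f"fused input has dim {fused.shape[0]}, classifier expects {params.W1.shape[0]}"
        )
    hidden = np.tanh(fused @ params.W1 + params.b1)
    return _softmax(hidden @ params.W2 + params.b2)


@dataclass
class LossConfig:
    """Distribution-loss configuration: lambda, per-class gamma, class counts."""

    class_counts: np.ndarray
    lam: float = 1e-5
    gamma: np.ndarray = field(default=None)

    def __post_init__(self):
        self.class_counts = np.asarray(self.class_counts, dtype=np.int64)
        if self.gamma is None:
            self.gamma = init_distribution_weights(self.class_counts)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if (self.gamma <= 0).any():
            raise ValueError("distribution weights must be positive")


def init_distribution_weights(class_counts) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    gamma_j is proportional to total/(M * count_j), so the class with more
    training samples always gets the strictly smaller weight; balanced
    counts give gamma = 1 for every class.
    """
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 1).any():
        raise ValueError("every class must have at least one training sample")
    raw = counts.sum() / (len(counts) * counts)
    return raw / raw.mean()


def distribution_loss(
    probabilities: np.ndarray,
    truth: np.ndarray,
    config: LossConfig,
    model_norm_sq: float = 0.0,
) -> float:
    """Mean of -gamma_{true class} * log p(true class), plus lambda * ||theta||^2.

    `truth` is one-hot (batch x M). Probabilities are clamped below at 1e-12
    before the log so the loss stays finite.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if probabilities.shape != truth.shape:
        raise ValueError(f"shape mismatch: probs {probabilities.shape} vs truth {truth.shape}")
    p_true = (probabilities * truth).sum(axis=1)
    w = truth @ config.gamma
    ce = -(w * np.log(np.clip(p_true, 1e-12, None))).mean()
    return float(ce + config.lam * model_norm_sq)


# ---------------------------------------------------------------------------
# end-to-end trainable model
# ---------------------------------------------------------------------------

_PROB_FLOOR = 1e-12


class FusionModel:
    """Trainable multifeature fusion recurrent attention network.

    Parameters
    ----------
    vocab_size, embed_dim : embedding table shape (padding row index 0).
    hidden_dim : LSTM units per direction (sentence vector has 2*hidden_dim).
    attn_dim : width of the attention tanh projection.
    feat_dim : length of the external feature vector (0 disables fusion).
    n_classes : output classes of the framing being trained.
    class_counts : training-class counts used to initialize gamma.
    """

    def __init__(
        self,
        vocab_size: int,
        embed_dim: int,
        hidden_dim: int,
        attn_dim: int,
        feat_dim: int,
        n_classes: int,
        class_counts,
        seed: int = 13,
        mlp_hidden: int | None = None,
        embedding: np.ndarray | None = None,
    ):
        rng = np.random.default_rng(seed)
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.attn_dim = attn_dim
        self.feat_dim = feat_dim
        self.n_classes = n_classes
        fused_dim = 2 * hidden_dim + feat_dim
        self.mlp_hidden = mlp_hidden or max(n_classes, fused_dim // 2)

        def U(k, *shape):
            return rng.uniform(-k, k, size=shape)

        kh = 1.0 / math.sqrt(hidden_dim)
        ka = 1.0 / math.sqrt(attn_dim)
        k1 = 1.0 / math.sqrt(fused_dim)
        k2 = 1.0 / math.sqrt(self.mlp_hidden)
        if embedding is None:
            embedding = rng.uniform(-0.25, 0.25, size=(vocab_size, embed_dim))
            embedding[0] = 0.0
        p: dict[str, Tensor] = {"emb": Tensor(np.array(embedding, dtype=np.float64), requires_grad=True)}
        for d in ("fwd", "bwd"):
            for g in GATES:
                p[f"{d}_W_{g}"] = Tensor(U(kh, embed_dim, hidden_dim), requires_grad=True)
                p[f"{d}_V_{g}"] = Tensor(U(kh, hidden_dim, hidden_dim), requires_grad=True)
                p[f"{d}_b_{g}"] = Tensor(U(kh, hidden_dim), requires_grad=True)
        p["attn_W"] = Tensor(U(ka, 2 * hidden_dim, attn_dim), requires_grad=True)
        p["attn_b"] = Tensor(U(ka, attn_dim), requires_grad=True)
        p["attn_u"] = Tensor(U(ka, attn_dim, 1), requires_grad=True)
        p["mlp_W1"] = Tensor(U(k1, fused_dim, self.mlp_hidden), requires_grad=True)
        p["mlp_b1"] = Tensor(U(k1, self.mlp_hidden), requires_grad=True)
        p["mlp_W2"] = Tensor(U(k2, self.mlp_hidden, n_classes), requires_grad=True)
        p["mlp_b2"] = Tensor(U(k2, n_classes), requires_grad=True)
        p["log_gamma"] = Tensor(np.log(init_distribution_weights(class_counts)), requires_grad=True)
        self.params = p
        # feature standardization (set from training data by the trainer)
        self.feat_mu = np.zeros(feat_dim)
        self.feat_sd = np.ones(feat_dim)

    # -- parameter bookkeeping ------------------------------------------------
    #: weight matrices covered by the L2 term; embeddings, biases and gamma excluded
    _L2_KEYS = staticmethod(
        lambda name: name.endswith(("_W_f", "_W_i", "_W_o", "_W_c", "_V_f", "_V_i", "_V_o", "_V_c"))
        or name in {"attn_W", "attn_u", "mlp_W1", "mlp_W2"}
    )

    def trainable(self) -> dict[str, Tensor]:
        return self.params

    def l2_norm_sq(self) -> Tensor:
        terms = [
            (t * t).sum() for name, t in self.params.items() if FusionModel._L2_KEYS(name)
        ]
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total

    def standardize(self, feats: np.ndarray) -> np.ndarray:
        if self.feat_dim == 0:
            return np.zeros((feats.shape[0], 0)) if feats.ndim == 2 else np.zeros(0)
        return (feats - self.feat_mu) / self.feat_sd

    # -- forward ---------------------------------------------------------------
    def _direction_pass(self, xs: list[Tensor], fmask: list[np.ndarray], direction: str):
        """Run one LSTM direction over per-step embeddings; returns per-step h."""
        p = self.params
        W = concat([p[f"{direction}_W_{g}"] for g in GATES], axis=1)
        V = concat([p[f"{direction}_V_{g}"] for g in GATES], axis=1)
        b = concat([p[f"{direction}_b_{g}"] for g in GATES], axis=0)
        H = self.hidden_dim
        B = xs[0].shape[0]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        order = range(len(xs)) if direction == "fwd" else range(len(xs) - 1, -1, -1)
        out: list[Tensor | None] = [None] * len(xs)
        for t in order:
            z = xs[t] @ W + h @ V + b
            f = z[:, 0:H].sigmoid()
            i = z[:, H : 2 * H].sigmoid()
            o = z[:, 2 * H : 3 * H].sigmoid()
            ct = z[:, 3 * H : 4 * H].tanh()
            c_new = f * c + i * ct
            h_new = o * c_new.tanh()
            m = fmask[t]  # (B,1) float; pad steps keep previous state
            h = h_new * m + h * (1.0 - m)
            c = c_new * m + c * (1.0 - m)
            out[t] = h * m  # pad positions emit zero vectors
        return out

    def forward(
        self,
        token_ids: np.ndarray,
        mask: np.ndarray,
        feats: np.ndarray,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Batched forward pass; returns (probabilities (B,M), attention (B,T)).

        `feats` must already be standardized. With dropout > 0 an inverted
        dropout mask (drawn from `rng`) is applied to the fused vector.
        """
        token_ids = np.asarray(token_ids)
        mask = np.asarray(mask, dtype=bool)
        B, T = token_ids.shape
        p = self.params
        H = self.hidden_dim

        xs = [gather_rows(p["emb"], token_ids[:, t]) for t in range(T)]
        fmask = [mask[:, t].astype(np.float64)[:, None] for t in range(T)]
        h_fwd = self._direction_pass(xs, fmask, "fwd")
        h_bwd = self._direction_pass(xs, fmask, "bwd")
        hs = [concat([h_fwd[t], h_bwd[t]], axis=1) for t in range(T)]  # (B, 2H) each

        scores = concat(
            [(hs[t] @ p["attn_W"] + p["attn_b"]).tanh() @ p["attn_u"] for t in range(T)], axis=1
        )  # (B, T)
        alpha = masked_softmax(scores, mask, axis=1)
        sentence = hs[0] * alpha[:, 0:1]
        for t in range(1, T):
            sentence = sentence + hs[t] * alpha[:, t : t + 1]

        fused = concat([sentence, Tensor(feats)], axis=1) if self.feat_dim else sentence
        if dropout > 0.0:
            if rng is None:
                raise ValueError("dropout requires an RNG")
            keep = (rng.random(fused.shape) >= dropout) / (1.0 - dropout)
            fused = fused * Tensor(keep)
        hidden = (fused @ p["mlp_W1"] + p["mlp_b1"]).tanh()
        logits = hidden @ p["mlp_W2"] + p["mlp_b2"]
        probs = masked_softmax(logits, np.ones_like(logits.data, dtype=bool), axis=1)
        return probs, alpha

    def loss(self, probs: Tensor, truth_onehot: np.ndarray, lam: float) -> Tensor:
        """Distribution-weighted cross-entropy + lambda * ||theta||^2 (a scalar Tensor)."""
        y = Tensor(np.asarray(truth_onehot, dtype=np.float64))
        gamma = self.params["log_gamma"].exp()
        p_true = (probs * y).sum(axis=1)
        w = (y * gamma).sum(axis=1)
        ce = -(w * p_true.clip_min(_PROB_FLOOR).log()).mean()
        if lam > 0.0:
            return ce + self.l2_norm_sq() * lam
        return ce

    # -- inference conveniences -------------------------------------------------
    def predict_proba(self, token_ids: np.ndarray, mask: np.ndarray, feats: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(token_ids, mask, self.standardize(feats))
        return probs.data

    def attention_weights(self, token_ids: np.ndarray, mask: np.ndarray, feats: np.ndarray) -> np.ndarray:
        _, alpha = self.forward(token_ids, mask, self.standardize(feats))
        return alpha.data

    @property
    def gamma(self) -> np.ndarray:
        return np.exp(self.params["log_gamma"].data)

    # -- interop with the functional reference path ------------------------------
    def lstm_params(self, direction: str) -> LSTMParams:
        p = self.params
        return LSTMParams(
            W={g: p[f"{direction}_W_{g}"].data for g in GATES},
            V={g: p[f"{direction}_V_{g}"].data for g in GATES},
            b={g: p[f"{direction}_b_{g}"].data for g in GATES},
        )

    def attention_params(self) -> AttentionParams:
        p = self.params
        return AttentionParams(W=p["attn_W"].data, b=p["attn_b"].data, u=p["attn_u"].data.ravel())

    def classifier_params(self) -> ClassifierParams:
        p = self.params
        return ClassifierParams(
            W1=p["mlp_W1"].data, b1=p["mlp_b1"].data, W2=p["mlp_W2"].data, b2=p["mlp_b2"].data
        )

    # -- state ---------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: t.data.copy() for name, t in self.params.items()}
        state["feat_mu"] = self.feat_mu.copy()
        state["feat_sd"] = self.feat_sd.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.params.items():
            t.data = np.array(state[name], dtype=np.float64)
        self.feat_mu = np.array(state["feat_mu"], dtype=np.float64)
        self.feat_sd = np.array(state["feat_sd"], dtype=np.float64)
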