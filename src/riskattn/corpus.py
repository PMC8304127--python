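"""Corpus data model: posts, label framings, tokenization, vocabulary, embeddings.

Posts carry a 4-class suicide-risk label ``a < b < c < d`` (low to high).
Two coarser framings are derived from it:

* **existence** — whether suicidal intention exists at all; only class ``a``
  maps to ``not_exist``.
* **urgency** — whether the poster needs urgent attention; classes ``c`` and
  ``d`` map to ``urgent`` (the published example table's convention, which
  is the one consistent with ordering urgency by risk).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RISK_CLASSES",
    "URGENT_CLASSES",
    "Post",
    "FramedLabels",
    "Vocabulary",
    "EmbeddingTable",
    "tokenize",
    "derive_framed_labels",
    "read_corpus",
    "write_corpus",
    "build_vocabulary",
    "load_word_vectors",
]

RISK_CLASSES = ("a", "b", "c", "d")

#: Risk classes collapsed to "urgent". The source study's prose and its
#: example table disagree; we follow the table (c, d -> urgent). Pass
#: ``urgent_classes=("a", "b")`` to derive_framed_labels for the other reading.
URGENT_CLASSES = ("c", "d")

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_INDEX = 0
UNK_INDEX = 1

# Words (incl. internal apostrophes), else any single non-space symbol.
# Punctuation and emoji must survive as standalone tokens: the symbolic
# feature extractor counts "?" and emoji tokens downstream.
_TOKEN_RE = re.compile(r"\w+(?:'\w+)*|[^\w\s]", re.UNICODE)


def tokenize(raw_text: str) -> list[str]:
    """Lowercase and split text into word, punctuation and emoji tokens.

    Deterministic and idempotent on rejoined output; never yields empty
    tokens. Empty input yields an empty list.
    """
    return _TOKEN_RE.findall(raw_text.lower())


@dataclass
class Post:
    """One social-media post with its 4-class risk label."""

    post_id: str
    raw_text: str
    risk_label: str
    tokens: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.risk_label not in RISK_CLASSES:
            raise ValueError(
                f"unknown risk label {self.risk_label!r} for post {self.post_id!r}; "
                f"expected one of {RISK_CLASSES}"
            )
        if not self.tokens:
            self.tokens = tokenize(self.raw_text)


@dataclass(frozen=True)
class FramedLabels:
    """The three label framings of one post."""

    risk: str
    existence: str  # "exist" | "not_exist"
    urgency: str  # "urgent" | "not_urgent"


def derive_framed_labels(risk: str, urgent_classes: tuple[str, ...] = URGENT_CLASSES) -> FramedLabels:
    """Collapse the 4-class risk label into the existence and urgency framings.

    existence is "not_exist" iff risk is class a; urgency is "urgent" iff
    risk is in `urgent_classes`.
    """
    if risk not in RISK_CLASSES:
        raise ValueError(f"unknown risk class {risk!r}")
    existence = "not_exist" if risk == "a" else "exist"
    urgency = "urgent" if risk in urgent_classes else "not_urgent"
    return FramedLabels(risk=risk, existence=existence, urgency=urgency)


def framing_class_index(post_or_risk, framing: str) -> int:
    """Integer class index of a post under a framing.

    risk: a..d -> 0..3; existence: not_exist=0, exist=1;
    urgency: not_urgent=0, urgent=1.
    """
    risk = post_or_risk.risk_label if isinstance(post_or_risk, Post) else post_or_risk
    labels = derive_framed_labels(risk)
    if framing == "risk":
        return RISK_CLASSES.index(risk)
    if framing == "existence":
        return int(labels.existence == "exist")
    if framing == "urgency":
        return int(labels.urgency == "urgent")
    raise ValueError(f"unknown framing {framing!r}")


def framing_num_classes(framing: str) -> int:
    return 4 if framing == "risk" else 2


def framing_class_names(framing: str) -> list[str]:
    if framing == "risk":
        return list(RISK_CLASSES)
    if framing == "existence":
        return ["not_exist", "exist"]
    if framing == "urgency":
        return ["not_urgent", "urgent"]
    raise ValueError(f"unknown framing {framing!r}")


# ---------------------------------------------------------------------------
# corpus I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "jsonl"


def read_corpus(path, format: str | None = None) -> list[Post]:
    """Read posts from JSONL ({"post_id", "text", "label"}) or 3-column TSV.

    TSV columns are (post_id, label, text). Malformed records raise a
    ValueError naming the line number; unknown labels name the value.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    posts: list[Post] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                if fmt == "jsonl":
                    rec = json.loads(line)
                    post_id, text, label = rec["post_id"], rec["text"], rec["label"]
                else:
                    post_id, label, text = line.split("\t", 2)
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from exc
            if label not in RISK_CLASSES:
                raise ValueError(
                    f"{path}:{lineno}: unknown risk label {label!r}; expected one of {RISK_CLASSES}"
                )
            posts.append(Post(post_id=str(post_id), raw_text=text, risk_label=label))
    return posts


def write_corpus(posts: list[Post], path, format: str | None = None) -> None:
    """Write posts back out; raw text round-trips byte-identically via JSONL."""
    path = Path(path)
    fmt = _infer_format(path, format)
    with path.open("w", encoding="utf-8") as fh:
        for post in posts:
            if fmt == "jsonl":
                fh.write(
                    json.dumps(
                        {"post_id": post.post_id, "text": post.raw_text, "label": post.risk_label},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
            else:
                if "\t" in post.raw_text or "\n" in post.raw_text:
                    raise ValueError(
                        f"post {post.post_id!r} contains tab/newline; use JSONL for lossless output"
                    )
                fh.write(f"{post.post_id}\t{post.risk_label}\t{post.raw_text}\n")


# ---------------------------------------------------------------------------
# vocabulary and pretrained vectors
# ---------------------------------------------------------------------------


class Vocabulary:
    """Token <-> index mapping with reserved padding (0) and unknown (1) slots."""

    def __init__(self, tokens: list[str]):
        self.index_to_token = [PAD_TOKEN, UNK_TOKEN] + list(tokens)
        self.token_to_index = {t: i for i, t in enumerate(self.index_to_token)}
        if len(self.token_to_index) != len(self.index_to_token):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.index_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)

    def encode(self, tokens: list[str]) -> np.ndarray:
        return np.array([self.index(t) for t in tokens], dtype=np.int64)


def build_vocabulary(posts: list[Post], min_count: int = 1) -> Vocabulary:
    """Index every token with corpus frequency >= min_count.

    Deterministic regardless of input order: retained tokens are sorted
    lexicographically. Below-threshold tokens map to the unknown index.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    for post in posts:
        for tok in post.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(t for t, c in counts.items() if c >= min_count)
    return Vocabulary(kept)


@dataclass
class EmbeddingTable:
    """|V| x D matrix of per-token input vectors; row order follows the vocabulary."""

    matrix: np.ndarray

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def random_embeddings(vocab: Vocabulary, dim: int = 300, seed: int = 13, scale: float = 0.25) -> EmbeddingTable:
    """Seeded uniform(-scale, scale) embeddings; the padding row is zero."""
    rng = np.random.default_rng(seed)
    mat = rng.uniform(-scale, scale, size=(len(vocab), dim))
    mat[PAD_INDEX] = 0.0
    return EmbeddingTable(matrix=mat)


def load_word_vectors(path, vocab: Vocabulary, seed: int = 13, scale: float = 0.25) -> EmbeddingTable:
    """Load pretrained vectors from the common text dialect (token v1 ... vD).

    Vocabulary tokens found in the file get the stored vector; the rest are
    drawn from a seeded uniform(-scale, scale) so out-of-file rows are
    reproducible. The dimension is inferred from the file; inconsistent row
    widths raise a ValueError.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            token, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
                if dim == 0:
                    raise ValueError(f"{path}:{lineno}: no vector components")
            elif len(values) != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} components, found {len(values)}"
                )
            if token in vocab:
                vectors[token] = np.array([float(v) for v in values])
    assert dim is not None, "empty word-vector file"
    table = random_embeddings(vocab, dim=dim, seed=seed, scale=scale)
    n_hit = 0
    for token, vec in vectors.items():
        table.matrix[vocab.index(token)] = vec
        n_hit += 1
    if n_hit == 0:
        warnings.warn(f"no vocabulary token found in {path}", stacklevel=2)
    return table
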