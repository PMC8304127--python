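"""Handcrafted linguistic features fused with the neural sentence vector.

Three blocks per post:

* **n-gram block** — bigram+trigram TF-IDF weights, compressed to K
  (default 50) dimensions with non-negative matrix factorization because
  the raw n-gram matrix is extremely sparse;
* **lexicon block** — counts of words in six emotion categories (positive,
  negative, sadness, anger, despair, fear) plus the post length in tokens;
* **symbolic block** — counts of first-person singular pronouns, question
  marks, and emoji. These mark self-orientation, rhetorical questioning,
  and expressed affect, all informative for risk assessment.

Counts are exact integers; any scaling happens downstream in the model and
is recorded with the trained checkpoint, so feature vectors stay auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.feature_extraction.text import CountVectorizer

from .corpus import Post

__all__ = [
    "DEFAULT_EMOTION_CATEGORIES",
    "FIRST_PERSON_PRONOUNS",
    "EmotionLexicon",
    "FeatureVector",
    "NGramModel",
    "FeatureExtractor",
    "load_lexicon",
    "fit_ngram_tfidf",
    "reduce_nmf",
    "lexicon_features",
    "symbolic_features",
    "assemble_features",
    "is_emoji",
]

DEFAULT_EMOTION_CATEGORIES = ("positive", "negative", "sadness", "anger", "despair", "fear")

#: First-person *singular* forms only; plural self-reference (we, us, our)
#: does not carry the self-orientation signal these features target.
FIRST_PERSON_PRONOUNS = frozenset({"i", "me", "my", "mine", "myself"})

# Unicode blocks that cover the emoji repertoire in practice. A token counts
# as an emoji when every character is emoji-related (joiners and variation
# selectors allowed) and at least one is a pictograph proper.
_EMOJI_RANGES = (
    (0x1F1E6, 0x1F1FF),  # regional indicators
    (0x1F300, 0x1F5FF),  # misc symbols and pictographs
    (0x1F600, 0x1F64F),  # emoticons
    (0x1F680, 0x1F6FF),  # transport
    (0x1F700, 0x1F77F),
    (0x1F900, 0x1F9FF),  # supplemental symbols
    (0x1FA70, 0x1FAFF),  # symbols extended-A
    (0x2600, 0x26FF),  # misc symbols
    (0x2700, 0x27BF),  # dingbats (incl. hearts)
    (0x2B00, 0x2BFF),
)
_EMOJI_MODIFIERS = frozenset({0x200D, 0xFE0E, 0xFE0F}) | set(range(0x1F3FB, 0x1F400))


def _is_emoji_char(cp: int) -> bool:
    return any(lo <= cp <= hi for lo, hi in _EMOJI_RANGES)


def is_emoji(token: str) -> bool:
    if not token:
        return False
    cps = [ord(c) for c in token]
    if not any(_is_emoji_char(cp) for cp in cps):
        return False
    return all(_is_emoji_char(cp) or cp in _EMOJI_MODIFIERS for cp in cps)


# ---------------------------------------------------------------------------
# emotion lexicon
# ---------------------------------------------------------------------------


@dataclass
class EmotionLexicon:
    """Word -> emotion-category table with case-insensitive lookup."""

    word_categories: dict[str, frozenset[str]]
    categories: tuple[str, ...] = DEFAULT_EMOTION_CATEGORIES

    def lookup(self, token: str) -> frozenset[str]:
        return self.word_categories.get(token.lower(), frozenset())

    def __len__(self) -> int:
        return len(self.word_categories)


def load_lexicon(path, categories: tuple[str, ...] = DEFAULT_EMOTION_CATEGORIES) -> EmotionLexicon:
    """Load a 3-column TSV lexicon: word <TAB> category <TAB> 0/1.

    Rows with flag 0 and categories outside `categories` are ignored, so a
    full association lexicon can be filtered down to the configured set.
    """
    cat_set = set(categories)
    table: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            word, category, flag = parts
            if flag.strip() == "1" and category in cat_set:
                table.setdefault(word.lower(), set()).add(category)
    return EmotionLexicon(
        word_categories={w: frozenset(c) for w, c in table.items()}, categories=categories
    )


def write_lexicon(lexicon: EmotionLexicon, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word in sorted(lexicon.word_categories):
            for cat in lexicon.categories:
                flag = 1 if cat in lexicon.word_categories[word] else 0
                fh.write(f"{word}\t{cat}\t{flag}\n")


# ---------------------------------------------------------------------------
# count features
# ---------------------------------------------------------------------------


def lexicon_features(post: Post, lexicon: EmotionLexicon) -> np.ndarray:
    """Per-category emotion-word counts plus post length (7 integers).

    A token belonging to several categories increments each of them; matching
    is token-exact (no stemming) so every count is auditable.
    """
    counts = np.zeros(len(lexicon.categories) + 1, dtype=np.int64)
    cat_index = {c: i for i, c in enumerate(lexicon.categories)}
    for tok in post.tokens:
        for cat in lexicon.lookup(tok):
            counts[cat_index[cat]] += 1
    counts[-1] = len(post.tokens)
    return counts


def symbolic_features(post: Post) -> np.ndarray:
    """(first-person singular pronouns, question marks, emoji) counts."""
    fp = sum(1 for t in post.tokens if t in FIRST_PERSON_PRONOUNS)
    qm = sum(1 for t in post.tokens if t == "?")
    em = sum(1 for t in post.tokens if is_emoji(t))
    return np.array([fp, qm, em], dtype=np.int64)


# ---------------------------------------------------------------------------
# n-gram TF-IDF + NMF
# ---------------------------------------------------------------------------


def _ngrams(tokens: list[str], orders: tuple[int, ...]) -> list[str]:
    out = []
    for n in orders:
        out.extend(" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1))
    return out


@dataclass
class NGramModel:
    """Fitted bigram/trigram TF-IDF vocabulary with an optional NMF basis.

    Conventions (recorded in `conventions`): tf is the raw in-post count,
    idf = log((1+N)/(1+df)) with no +1 added after the log, so n-grams
    occurring in every document get weight exactly 0.
    """

    orders: tuple[int, ...]
    min_df: int
    vocabulary: dict[str, int]
    df: np.ndarray  # document frequency per retained n-gram
    n_docs: int
    k: int | None = None
    basis: np.ndarray | None = None  # (k, n_features), non-negative
    seed: int | None = None
    conventions: dict = field(
        default_factory=lambda: {"tf": "raw_count", "idf": "log((1+N)/(1+df))", "post_log_plus1": False}
    )
    _chol: np.ndarray | None = field(default=None, repr=False)

    @property
    def idf(self) -> np.ndarray:
        return np.log((1.0 + self.n_docs) / (1.0 + self.df))

    @property
    def n_features(self) -> int:
        return len(self.vocabulary)

    def transform(self, posts: list[Post]) -> sp.csr_matrix:
        """TF-IDF matrix (posts x retained n-grams); unseen n-grams are dropped."""
        rows, cols, vals = [], [], []
        for i, post in enumerate(posts):
            counts: dict[int, int] = {}
            for g in _ngrams(post.tokens, self.orders):
                j = self.vocabulary.get(g)
                if j is not None:
                    counts[j] = counts.get(j, 0) + 1
            for j, c in counts.items():
                rows.append(i)
                cols.append(j)
                vals.append(c)
        tf = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(posts), self.n_features), dtype=np.float64
        )
        return tf.multiply(self.idf).tocsr()

    # -- NMF ----------------------------------------------------------------
    def fit_nmf(self, tfidf: sp.csr_matrix, k: int = 50, seed: int = 13, max_iter: int = 400):
        """Factorize the training TF-IDF matrix; returns the post factors (n x k)."""
        factors, basis = reduce_nmf(tfidf, k=k, seed=seed, max_iter=max_iter)
        self.k, self.basis, self.seed = k, basis, seed
        self._chol = None
        return factors

    def _basis_cholesky(self) -> np.ndarray:
        if self.basis is None:
            raise ValueError("n-gram model has no fitted NMF basis; call fit_nmf first")
        if self._chol is None:
            gram = self.basis @ self.basis.T
            gram[np.diag_indices_from(gram)] += 1e-10 * max(1.0, np.trace(gram))
            self._chol = cholesky(gram, lower=True)
        return self._chol

    def project(self, tfidf_rows: sp.csr_matrix) -> np.ndarray:
        """Non-negative least-squares projection of TF-IDF rows onto the basis.

        Solves min_{w >= 0} ||x - w B|| per row via the Gram-reduced normal
        equations, so the cost is independent of the n-gram count after the
        one-time Cholesky. A zero row projects to exactly zero.
        """
        R = self._basis_cholesky()
        out = np.zeros((tfidf_rows.shape[0], self.k), dtype=np.float64)
        for i in range(tfidf_rows.shape[0]):
            x = tfidf_rows.getrow(i)
            if x.nnz == 0:
                continue
            f = self.basis @ x.T.toarray().ravel()
            b = solve_triangular(R, f, lower=True)
            out[i], _ = nnls(R.T, b)
        return out


def fit_ngram_tfidf(
    posts: list[Post], orders: tuple[int, ...] = (2, 3), min_df: int = 2
) -> tuple[NGramModel, sp.csr_matrix]:
    """Fit the n-gram vocabulary and return (model, training TF-IDF matrix).

    One combined vocabulary covers all requested orders (a single TF-IDF
    matrix feeds one NMF). Column order is lexicographic, so the fit is
    deterministic regardless of corpus order.
    """
    if not posts:
        raise ValueError("cannot fit n-gram model on an empty corpus")
    orders = tuple(sorted(orders))
    vectorizer = CountVectorizer(
        analyzer=lambda tokens: _ngrams(tokens, orders), min_df=min_df, lowercase=False
    )
    try:
        counts = vectorizer.fit_transform([p.tokens for p in posts])
    except ValueError as exc:  # no n-gram reaches min_df
        raise ValueError(f"no n-gram with document frequency >= {min_df}") from exc
    df = np.asarray((counts > 0).sum(axis=0)).ravel().astype(np.int64)
    model = NGramModel(
        orders=orders,
        min_df=min_df,
        vocabulary={g: int(j) for g, j in vectorizer.vocabulary_.items()},
        df=df,
        n_docs=len(posts),
    )
    tfidf = counts.astype(np.float64).multiply(model.idf).tocsr()
    return model, tfidf


def reduce_nmf(
    tfidf_matrix, k: int = 50, seed: int = 13, max_iter: int = 400
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative matrix factorization X ~ W B with multiplicative updates.

    Returns (post factors W: n x k, basis B: k x n_features), both
    element-wise non-negative, from a seeded random initialization.
    """
    n, m = tfidf_matrix.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds matrix dimensions {tfidf_matrix.shape}")
    if sp.issparse(tfidf_matrix):
        if (tfidf_matrix.data < 0).any():
            raise ValueError("TF-IDF matrix must be non-negative")
    elif (np.asarray(tfidf_matrix) < 0).any():
        raise ValueError("TF-IDF matrix must be non-negative")
    nmf = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=1e-9,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        factors = nmf.fit_transform(tfidf_matrix)
    return factors, nmf.components_


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """External feature vector of one post: [ngram | lexicon | symbolic]."""

    ngram: np.ndarray  # K non-negative reals
    lexicon: np.ndarray  # 7 non-negative integers
    symbolic: np.ndarray  # 3 non-negative integers

    def concat(self) -> np.ndarray:
        return np.concatenate([self.ngram, self.lexicon.astype(np.float64), self.symbolic.astype(np.float64)])

    def __len__(self) -> int:
        return len(self.ngram) + len(self.lexicon) + len(self.symbolic)


def assemble_features(post: Post, ngram_model: NGramModel, lexicon: EmotionLexicon) -> FeatureVector:
    """Featurize one post; with the default K=50 the vector has 50+7+3 = 60 entries."""
    if ngram_model.basis is None:
        raise ValueError("n-gram model is not fitted (no NMF basis)")
    ngram_block = ngram_model.project(ngram_model.transform([post]))[0]
    return FeatureVector(
        ngram=ngram_block,
        lexicon=lexicon_features(post, lexicon),
        symbolic=symbolic_features(post),
    )


class FeatureExtractor:
    """Fitted feature pipeline: n-gram TF-IDF -> NMF block + count blocks."""

    def __init__(self, ngram_model: NGramModel, lexicon: EmotionLexicon):
        self.ngram_model = ngram_model
        self.lexicon = lexicon

    @classmethod
    def fit(
        cls,
        posts: list[Post],
        lexicon: EmotionLexicon,
        orders: tuple[int, ...] = (2, 3),
        min_df: int = 2,
        k: int = 50,
        seed: int = 13,
    ) -> tuple["FeatureExtractor", list[FeatureVector]]:
        """Fit on a training corpus; returns the extractor and training vectors.

        The training posts' n-gram factors come straight from the NMF fit
        (not re-projected), matching how the factorization defines them.
        """
        model, tfidf = fit_ngram_tfidf(posts, orders=orders, min_df=min_df)
        factors = model.fit_nmf(tfidf, k=k, seed=seed)
        extractor = cls(model, lexicon)
        vectors = [
            FeatureVector(
                ngram=factors[i],
                lexicon=lexicon_features(p, lexicon),
                symbolic=symbolic_features(p),
            )
            for i, p in enumerate(posts)
        ]
        return extractor, vectors

    def transform(self, post: Post) -> FeatureVector:
        return assemble_features(post, self.ngram_model, self.lexicon)

    def transform_many(self, posts: list[Post]) -> list[FeatureVector]:
        tfidf = self.ngram_model.transform(posts)
        blocks = self.ngram_model.project(tfidf)
        return [
            FeatureVector(
                ngram=blocks[i],
                lexicon=lexicon_features(p, self.lexicon),
                symbolic=symbolic_features(p),
            )
            for i, p in enumerate(posts)
        ]

    # -- serialization -------------------------------------------------------
    def save(self, path) -> None:
        """Serialize to a single .npz archive (n-gram map, df, basis, config, lexicon)."""
        vocab_items = sorted(self.ngram_model.vocabulary.items(), key=lambda kv: kv[1])
        meta = {
            "orders": list(self.ngram_model.orders),
            "min_df": self.ngram_model.min_df,
            "n_docs": self.ngram_model.n_docs,
            "k": self.ngram_model.k,
            "seed": self.ngram_model.seed,
            "conventions": self.ngram_model.conventions,
            "categories": list(self.lexicon.categories),
            "lexicon": {w: sorted(c) for w, c in self.lexicon.word_categories.items()},
        }
        np.savez(
            path,
            ngrams=np.array([g for g, _ in vocab_items], dtype=object),
            df=self.ngram_model.df,
            basis=self.ngram_model.basis if self.ngram_model.basis is not None else np.zeros((0, 0)),
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path) -> "FeatureExtractor":
        with np.load(path, allow_pickle=True) as npz:
            meta = json.loads(str(npz["meta"]))
            ngrams = [str(g) for g in npz["ngrams"]]
            basis = npz["basis"]
            df = npz["df"]
        model = NGramModel(
            orders=tuple(meta["orders"]),
            min_df=meta["min_df"],
            vocabulary={g: j for j, g in enumerate(ngrams)},
            df=df,
            n_docs=meta["n_docs"],
            k=meta["k"],
            basis=basis if basis.size else None,
            seed=meta["seed"],
            conventions=meta["conventions"],
        )
        lexicon = EmotionLexicon(
            word_categories={w: frozenset(c) for w, c in meta["lexicon"].items()},
            categories=tuple(meta["categories"]),
        )
        return cls(model, lexicon)
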