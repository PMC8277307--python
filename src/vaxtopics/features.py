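"""Tweet-aware tokenization and sparse count features.

Short social-media texts are segmented into tokens that keep ``#hashtag``
and ``@mention`` markers intact, plain words are lowercased and stop words
dropped, and each text is represented by a sparse vector of frequencies of
every unigram, adjacent-pair bigram, hashtag and mention in the corpus
vocabulary.  Column order is lexicographic, so a vocabulary built twice on
the same corpus is identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DEFAULT_STOPWORDS",
    "TOKEN_KINDS",
    "tokenize",
    "Vocabulary",
    "build_vocabulary",
    "vectorize",
    "TweetVectorizer",
]

#: Standard English stop-word list; callers may augment it.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)

TOKEN_KINDS = ("unigram", "bigram", "hashtag", "mention")

# Hashtags and mentions are single tokens; plain words keep internal
# apostrophes (don't) and digits (sb276); everything else is a separator.
_TOKEN_RE = re.compile(r"#\w+|@\w+|[A-Za-z0-9_']+")


def tokenize(text: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Segment tweet-style text into lowercase tokens.

    ``#tag`` and ``@user`` survive as single tokens; plain-word tokens that
    are stop words are removed.  Empty text yields an empty list.

    Parameters
    ----------
    text:
        The raw tweet text.
    stopwords:
        Stop words to drop (plain words only).  ``None`` uses the standard
        English list.
    """
    stop = DEFAULT_STOPWORDS if stopwords is None else frozenset(stopwords)
    out = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0).lower()
        if tok[0] in "#@":
            out.append(tok)
        elif tok not in stop:
            out.append(tok)
    return out


def token_kind(token: str) -> str:
    """Classify a vocabulary entry as unigram, bigram, hashtag or mention."""
    if " " in token:
        return "bigram"
    if token.startswith("#"):
        return "hashtag"
    if token.startswith("@"):
        return "mention"
    return "unigram"


def _terms(tokens: Sequence[str]) -> list[str]:
    """Tokens plus adjacent-pair bigrams (bigrams joined with a space)."""
    terms = list(tokens)
    terms.extend(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    return terms


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token -> column-index map with a kind per entry."""

    index: dict[str, int]
    kinds: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.kinds:
            ordered = sorted(self.index, key=self.index.get)
            object.__setattr__(self, "kinds", tuple(token_kind(t) for t in ordered))
        if sorted(self.index.values()) != list(range(len(self.index))):
            raise ValueError("vocabulary indices must be a bijection onto 0..size-1")

    @property
    def size(self) -> int:
        return len(self.index)

    @property
    def tokens(self) -> list[str]:
        """Tokens in column order."""
        return sorted(self.index, key=self.index.get)

    def kind_of(self, token: str) -> str:
        return self.kinds[self.index[token]]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.index)


def build_vocabulary(corpus: Sequence[Sequence[str]]) -> Vocabulary:
    """Build the lexicographically ordered vocabulary of a tokenized corpus.

    Every unigram, adjacent-pair bigram, hashtag and mention occurring in
    ``corpus`` gets one column.  An empty corpus (or one yielding no terms
    at all) is rejected.
    """
    if not corpus:
        raise ValueError("corpus is empty; cannot build a vocabulary")
    seen: set[str] = set()
    for tokens in corpus:
        seen.update(_terms(tokens))
    if not seen:
        raise ValueError("corpus yields an empty vocabulary (all tokens removed?)")
    return Vocabulary({tok: i for i, tok in enumerate(sorted(seen))})


def vectorize(corpus: Sequence[Sequence[str]], vocab: Vocabulary) -> sp.csr_matrix:
    """Sparse count matrix: entry (i, j) = frequency of vocab term j in text i.

    Terms absent from ``vocab`` are ignored.
    """
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    lookup = vocab.index
    for tokens in corpus:
        row: dict[int, int] = {}
        for term in _terms(tokens):
            j = lookup.get(term)
            if j is not None:
                row[j] = row.get(j, 0) + 1
        indices.extend(row.keys())
        data.extend(row.values())
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.asarray(data, dtype=np.int64), np.asarray(indices, dtype=np.int32), indptr),
        shape=(len(corpus), vocab.size),
    )
    X.sum_duplicates()
    return X


class TweetVectorizer(TransformerMixin, BaseEstimator):
    """Tokenize tweets and produce unigram/bigram/hashtag/mention counts.

    A scikit-learn transformer: ``fit`` learns the vocabulary from raw
    texts, ``transform`` maps raw texts to a sparse count matrix over it.

    Parameters
    ----------
    stopwords : iterable of str, optional
        Stop-word list; ``None`` means the standard English list.
    extra_stopwords : iterable of str
        Augmentation added to the base list (tweet corpora typically need
        platform-specific additions such as "rt" or "amp").

    Attributes
    ----------
    vocabulary_ : Vocabulary
        The fitted token -> column map with per-entry kinds.
    """

    def __init__(
        self,
        stopwords: Iterable[str] | None = None,
        extra_stopwords: Iterable[str] = (),
    ) -> None:
        self.stopwords = stopwords
        self.extra_stopwords = extra_stopwords

    def _stop(self) -> frozenset[str]:
        base = DEFAULT_STOPWORDS if self.stopwords is None else frozenset(self.stopwords)
        return base | frozenset(self.extra_stopwords)

    def tokenize(self, text: str) -> list[str]:
        return tokenize(text, self._stop())

    def fit(self, X: Sequence[str], y=None) -> "TweetVectorizer":
        stop = self._stop()
        self.vocabulary_ = build_vocabulary([tokenize(t, stop) for t in X])
        return self

    def transform(self, X: Sequence[str]) -> sp.csr_matrix:
        check_is_fitted(self, "vocabulary_")
        stop = self._stop()
        return vectorize([tokenize(t, stop) for t in X], self.vocabulary_)
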