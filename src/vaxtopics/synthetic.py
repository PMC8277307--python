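"""Synthetic tweet-like corpora and planted cluster geometries.

Real vaccine-debate tweets cannot be redistributed, so the pipeline is
exercised on generated corpora carrying the statistical structure the
analysis assumes: three stance classes, per-stance planted topics whose
term distributions are separated by a controllable amount, duplicate
records retrieved under several keywords, retweets embedding originals,
and "handle-only" closed-loop conversation clusters made entirely of
@-mentions.

The token model: each stance has ``n_topics_per_stance`` topics with
disjoint topic vocabularies plus one shared pool.  A tweet from topic *t*
draws tokens from a two-component mixture — topic vocabulary with weight
``separation / (1 + separation)``, shared pool otherwise — so that
``separation = 0`` makes all topics statistically indistinguishable and
growing separation moves the planted term distributions apart.
``dispersion`` jitters the per-tweet mixture weight (a Beta draw with mean
at the topic weight and concentration ``1 / dispersion``), creating
within-topic variability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .ingest import TweetRecord

__all__ = [
    "CorpusSpec",
    "SyntheticTweet",
    "PlantedGeometry",
    "generate_corpus",
    "generate_geometry",
]

_STANCE_ORDER = ("pro", "anti", "neutral")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus.

    Defaults reproduce the annotated-set conditions of the study design
    this package targets: class counts 1639 pro / 1550 anti / 2422
    neutral, three topics per stance, and moderate topic separation.

    Parameters
    ----------
    n_per_class:
        Base tweet counts for (pro, anti, neutral).
    n_topics_per_stance:
        Planted topics per stance (>= 1).
    vocab_size_per_topic, shared_vocab_size:
        Sizes of each disjoint topic vocabulary and of the shared pool.
    separation:
        Nonnegative control of the distance between planted topic term
        distributions; 0 makes topics indistinguishable.
    dispersion:
        Nonnegative control of within-topic variability of the per-tweet
        topic-vocabulary weight.
    duplicate_rate, retweet_rate:
        Fractions in [0, 1) of base tweets re-emitted verbatim under a
        second keyword channel, resp. wrapped as retweets.
    handle_cluster_sizes:
        Sizes of injected closed-loop mention clusters (may be empty).
    separation_per_stance:
        Optional (pro, anti, neutral) triple overriding ``separation``
        per stance, for corpora whose groups differ in planted topic
        separation.
    topic_weights:
        Optional relative sizes of the planted topics within each stance
        (length ``n_topics_per_stance``, positive, normalized
        internally).  Default: equal sizes.  Tweets are allocated to
        topics by largest remainder, so topic sizes are deterministic.
    tokens_per_tweet:
        Mean tweet length in tokens (Poisson, floor 3).
    hashtag_fraction:
        Fraction of each topic vocabulary rendered as ``#`` hashtags.
    mention_rate:
        Per-token probability of emitting a random ``@`` mention instead.
    """

    n_per_class: tuple[int, int, int] = (1639, 1550, 2422)
    n_topics_per_stance: int = 3
    vocab_size_per_topic: int = 40
    shared_vocab_size: int = 80
    separation: float = 2.0
    dispersion: float = 0.1
    duplicate_rate: float = 0.0
    retweet_rate: float = 0.0
    handle_cluster_sizes: tuple[int, ...] = ()
    separation_per_stance: tuple[float, float, float] | None = None
    topic_weights: tuple[float, ...] | None = None
    seed: int = 0
    tokens_per_tweet: int = 12
    hashtag_fraction: float = 0.15
    mention_rate: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_class", tuple(self.n_per_class))
        object.__setattr__(self, "handle_cluster_sizes", tuple(self.handle_cluster_sizes))
        if len(self.n_per_class) != 3 or any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class: needs three nonnegative counts (pro, anti, neutral)")
        if self.n_topics_per_stance < 1:
            raise ValueError("n_topics_per_stance: must be >= 1")
        if self.vocab_size_per_topic < 1:
            raise ValueError("vocab_size_per_topic: must be >= 1")
        if self.shared_vocab_size < 1:
            raise ValueError("shared_vocab_size: must be >= 1")
        if self.separation < 0:
            raise ValueError("separation: must be nonnegative")
        if self.separation_per_stance is not None:
            sps = tuple(float(s) for s in self.separation_per_stance)
            object.__setattr__(self, "separation_per_stance", sps)
            if len(sps) != 3 or any(s < 0 for s in sps):
                raise ValueError(
                    "separation_per_stance: needs three nonnegative reals (pro, anti, neutral)"
                )
        if self.dispersion < 0:
            raise ValueError("dispersion: must be nonnegative")
        for name in ("duplicate_rate", "retweet_rate", "mention_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name}: must lie in [0, 1)")
        if any(s < 1 for s in self.handle_cluster_sizes):
            raise ValueError("handle_cluster_sizes: sizes must be >= 1")
        if self.topic_weights is not None:
            tw = tuple(float(w) for w in self.topic_weights)
            object.__setattr__(self, "topic_weights", tw)
            if len(tw) != self.n_topics_per_stance or any(w <= 0 for w in tw):
                raise ValueError(
                    "topic_weights: needs n_topics_per_stance positive weights"
                )
        if self.tokens_per_tweet < 1:
            raise ValueError("tokens_per_tweet: must be >= 1")
        if not 0 <= self.hashtag_fraction <= 1:
            raise ValueError("hashtag_fraction: must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticTweet:
    """A generated tweet with its ground truth."""

    tweet_id: str
    text: str
    true_stance: str
    true_topic: int | None
    is_retweet: bool = False
    original_tweet_id: str | None = None
    source_keyword: str | None = None

    def to_record(self) -> TweetRecord:
        return TweetRecord(
            tweet_id=self.tweet_id,
            text=self.text,
            label=self.true_stance,
            true_topic=self.true_topic,
            is_retweet=self.is_retweet,
            original_tweet_id=self.original_tweet_id,
            source_keyword=self.source_keyword,
        )


def _topic_vocab(stance: str, topic: int, spec: CorpusSpec) -> list[str]:
    n_hash = int(round(spec.hashtag_fraction * spec.vocab_size_per_topic))
    vocab = []
    for j in range(spec.vocab_size_per_topic):
        stem = f"{stance}t{topic}w{j}"
        vocab.append(f"#{stem}" if j < n_hash else stem)
    return vocab


def _tweet_tokens(
    rng: np.random.Generator,
    topic_vocab: Sequence[str],
    shared_vocab: Sequence[str],
    spec: CorpusSpec,
    separation: float,
) -> list[str]:
    n = max(3, int(rng.poisson(spec.tokens_per_tweet)))
    p_topic = separation / (1.0 + separation)
    if spec.dispersion > 0 and 0 < p_topic < 1:
        kappa = 1.0 / spec.dispersion
        w = float(rng.beta(p_topic * kappa, (1.0 - p_topic) * kappa))
    else:
        w = p_topic
    tokens = []
    for _ in range(n):
        if rng.random() < spec.mention_rate:
            tokens.append(f"@user{int(rng.integers(200))}")
        elif rng.random() < w:
            tokens.append(topic_vocab[int(rng.integers(len(topic_vocab)))])
        else:
            tokens.append(shared_vocab[int(rng.integers(len(shared_vocab)))])
    return tokens


def _allocate_topics(n: int, spec: CorpusSpec) -> list[int]:
    """Deterministic topic label sequence by largest-remainder allocation."""
    k = spec.n_topics_per_stance
    weights = np.asarray(spec.topic_weights or (1.0,) * k, dtype=float)
    quotas = n * weights / weights.sum()
    counts = np.floor(quotas).astype(int)
    order = np.argsort(-(quotas - counts), kind="stable")
    for t in order[: n - counts.sum()]:
        counts[t] += 1
    return [t for t in range(k) for _ in range(counts[t])]


def generate_corpus(
    spec: CorpusSpec, return_log: bool = False
) -> list[SyntheticTweet] | tuple[list[SyntheticTweet], dict]:
    """Generate a synthetic corpus under ``spec``; deterministic per seed.

    Returns exactly ``sum(n_per_class)`` base tweets plus injected
    duplicates (verbatim re-emissions under a second keyword channel),
    retweets (new IDs referencing existing originals) and handle-only
    clusters.  With ``return_log=True`` also returns a generator log with
    the injected counts.
    """
    rng = np.random.default_rng(spec.seed)
    shared_vocab = [f"sharedw{j}" for j in range(spec.shared_vocab_size)]
    counter = 0
    tweets: list[SyntheticTweet] = []

    separations = spec.separation_per_stance or (spec.separation,) * 3
    for stance, n, sep in zip(_STANCE_ORDER, spec.n_per_class, separations):
        topic_vocabs = [
            _topic_vocab(stance, t, spec) for t in range(spec.n_topics_per_stance)
        ]
        topic_seq = _allocate_topics(n, spec)
        for i in range(n):
            topic = topic_seq[i]
            toks = _tweet_tokens(rng, topic_vocabs[topic], shared_vocab, spec, sep)
            tweets.append(
                SyntheticTweet(
                    tweet_id=f"t{counter:07d}",
                    text=" ".join(toks),
                    true_stance=stance,
                    true_topic=topic,
                    source_keyword="kw0",
                )
            )
            counter += 1

    n_base = len(tweets)
    log = {"n_base": n_base, "n_duplicates": 0, "n_retweets": 0, "n_handle_tweets": 0}

    # Duplicates: the same tweet retrieved again under a second keyword.
    n_dup = int(round(spec.duplicate_rate * n_base))
    if n_dup:
        picks = rng.choice(n_base, size=n_dup, replace=False)
        for i in sorted(int(p) for p in picks):
            src = tweets[i]
            tweets.append(
                SyntheticTweet(
                    tweet_id=src.tweet_id,
                    text=src.text,
                    true_stance=src.true_stance,
                    true_topic=src.true_topic,
                    is_retweet=src.is_retweet,
                    original_tweet_id=src.original_tweet_id,
                    source_keyword="kw1",
                )
            )
        log["n_duplicates"] = n_dup

    # Retweets embedding an existing original.
    n_rt = int(round(spec.retweet_rate * n_base))
    if n_rt:
        picks = rng.choice(n_base, size=n_rt, replace=True)
        for p in picks:
            src = tweets[int(p)]
            tweets.append(
                SyntheticTweet(
                    tweet_id=f"t{counter:07d}",
                    text=f"rt @user{int(rng.integers(200))} {src.text}",
                    true_stance=src.true_stance,
                    true_topic=src.true_topic,
                    is_retweet=True,
                    original_tweet_id=src.tweet_id,
                    source_keyword="kw0",
                )
            )
            counter += 1
        log["n_retweets"] = n_rt

    # Handle-only clusters: closed-loop exchanges between a few accounts.
    # Their text consists entirely of handles, so the top-terms ranking of
    # such a cluster is exhausted by mention tokens and the handle filter
    # can recognise it.
    for ci, size in enumerate(spec.handle_cluster_sizes):
        accounts = [f"@loop{ci}a{j}" for j in range(4)]
        stance = ("pro", "anti")[ci % 2]
        for _ in range(size):
            n = max(3, int(rng.poisson(spec.tokens_per_tweet)))
            toks = [accounts[int(rng.integers(len(accounts)))] for _ in range(n)]
            tweets.append(
                SyntheticTweet(
                    tweet_id=f"t{counter:07d}",
                    text=" ".join(toks),
                    true_stance=stance,
                    true_topic=None,
                    source_keyword="kw0",
                )
            )
            counter += 1
            log["n_handle_tweets"] += 1

    return (tweets, log) if return_log else tweets


def write_synthetic_corpus(
    tweets: Sequence[SyntheticTweet], path: str | Path, log: dict | None = None
) -> None:
    """Write tweets as JSON-lines; optionally a generator log alongside."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for tw in tweets:
            obj = {
                "tweet_id": tw.tweet_id,
                "text": tw.text,
                "label": tw.true_stance,
                "true_topic": tw.true_topic,
                "is_retweet": tw.is_retweet,
                "original_tweet_id": tw.original_tweet_id,
                "source_keyword": tw.source_keyword,
            }
            fh.write(json.dumps(obj, sort_keys=True))
            fh.write("\n")
    if log is not None:
        path.with_suffix(".log.json").write_text(json.dumps(log, sort_keys=True, indent=2))


@dataclass(frozen=True)
class PlantedGeometry:
    """Points with known cluster structure for testing geometry statistics."""

    points: np.ndarray
    assignment: np.ndarray
    centroids_true: np.ndarray
    dispersions_true: np.ndarray

    def __post_init__(self) -> None:
        if len(self.points) != len(self.assignment):
            raise ValueError("every point needs exactly one cluster index")
        if len(np.unique(self.assignment)) != len(self.centroids_true):
            raise ValueError("clusters must be non-empty")


def generate_geometry(
    n_clusters: int,
    centroid_distance: float,
    dispersion: float,
    size_per_cluster: int,
    dim: int,
    seed: int = 0,
) -> PlantedGeometry:
    """Isotropic Gaussian blobs around pairwise-equidistant centroids.

    Centroids sit at the vertices of a regular simplex with edge length
    ``centroid_distance`` (requires ``dim >= n_clusters``); each blob has
    isotropic spread ``dispersion``.  Deterministic per seed.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if size_per_cluster < 1:
        raise ValueError("size_per_cluster must be >= 1")
    if n_clusters > 1 and dim < n_clusters:
        raise ValueError("dim must be >= n_clusters to place equidistant centroids")
    rng = np.random.default_rng(seed)
    centroids = np.zeros((n_clusters, dim))
    if n_clusters > 1:
        # scaled identity rows: pairwise distance = edge * sqrt(2) / sqrt(2)
        for c in range(n_clusters):
            centroids[c, c] = centroid_distance / math.sqrt(2.0)
    points = np.vstack(
        [
            centroids[c] + dispersion * rng.standard_normal((size_per_cluster, dim))
            for c in range(n_clusters)
        ]
    )
    assignment = np.repeat(np.arange(n_clusters), size_per_cluster)
    return PlantedGeometry(
        points=points,
        assignment=assignment,
        centroids_true=centroids,
        dispersions_true=np.full(n_clusters, float(dispersion)),
    )
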