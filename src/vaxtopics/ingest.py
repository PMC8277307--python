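"""Collection hygiene and corpus I/O.

Keyword-driven retrieval of short texts needs two cleanup computations
before any modelling: dropping search keywords whose median weekly yield is
zero (they no longer index live discourse), and de-duplicating records
retrieved under several keywords by their unique IDs, registering the
original embedded in every retweet as it streams past.
"""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "KeywordLog",
    "TweetRecord",
    "prune_keywords",
    "deduplicate",
    "read_corpus",
    "write_corpus",
    "read_keyword_logs",
]

STANCES = ("anti", "pro", "neutral")


@dataclass(frozen=True)
class KeywordLog:
    """Weekly retrieval counts for one search keyword."""

    keyword: str
    weekly_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(self.weekly_counts)
        object.__setattr__(self, "weekly_counts", counts)
        if not counts:
            raise ValueError(f"keyword {self.keyword!r}: weekly_counts is empty")
        if any(c < 0 for c in counts):
            raise ValueError(f"keyword {self.keyword!r}: negative weekly count")


@dataclass
class TweetRecord:
    """One short text: unique ID, body, optional stance label and linkage."""

    tweet_id: str
    text: str
    label: str | None = None
    true_topic: int | None = None
    is_retweet: bool = False
    original_tweet_id: str | None = None
    source_keyword: str | None = None

    def __post_init__(self) -> None:
        if not self.tweet_id:
            raise ValueError("tweet_id must be non-empty")
        if self.label is not None and self.label not in STANCES:
            raise ValueError(f"label must be one of {STANCES} or None, got {self.label!r}")


def prune_keywords(logs: Sequence[KeywordLog]) -> list[str]:
    """Keep keywords whose median weekly count is strictly positive.

    The median of an even-length count vector is the mean of the two middle
    order statistics, so e.g. counts ``[0, 0, 1, 5]`` (median 0.5) survive.
    Input order is preserved.
    """
    return [log.keyword for log in logs if statistics.median(log.weekly_counts) > 0]


def deduplicate(stream: Iterable[TweetRecord]) -> tuple[list[TweetRecord], int]:
    """Drop records whose unique ID was already encountered, streaming.

    The first occurrence of each ``tweet_id`` is kept in first-seen order.
    A retweet embeds its original: the original's ID is checked against the
    seen set — if already registered the retweet is redundant and dropped,
    otherwise both IDs are registered and the retweet record is kept.

    Returns the unique records and the number dropped.
    """
    seen: set[str] = set()
    unique: list[TweetRecord] = []
    n_dropped = 0
    for rec in stream:
        if not rec.tweet_id:
            raise ValueError("record with empty tweet_id")
        redundant = rec.tweet_id in seen or (
            rec.is_retweet
            and rec.original_tweet_id is not None
            and rec.original_tweet_id in seen
        )
        seen.add(rec.tweet_id)
        if rec.is_retweet and rec.original_tweet_id:
            seen.add(rec.original_tweet_id)
        if redundant:
            n_dropped += 1
        else:
            unique.append(rec)
    return unique, n_dropped


_FIELDS = (
    "tweet_id",
    "text",
    "label",
    "true_topic",
    "is_retweet",
    "original_tweet_id",
    "source_keyword",
)


def write_corpus(records: Iterable[TweetRecord], path: str | Path) -> None:
    """Write records as JSON-lines, one object per record."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(asdict(rec), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def read_corpus(path: str | Path) -> list[TweetRecord]:
    """Read a JSON-lines corpus; a malformed line raises with its number."""
    records: list[TweetRecord] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                rec = TweetRecord(**{k: obj.get(k) for k in _FIELDS if k in obj})
            except (json.JSONDecodeError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed corpus record at line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def read_keyword_logs(path: str | Path) -> list[KeywordLog]:
    """Read keyword logs from CSV with columns keyword, week, count."""
    by_kw: dict[str, list[tuple[int, int]]] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            by_kw.setdefault(row["keyword"], []).append(
                (int(row["week"]), int(row["count"]))
            )
    return [
        KeywordLog(kw, tuple(c for _, c in sorted(weeks)))
        for kw, weeks in by_kw.items()
    ]
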