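"""Tweet/user record types, JSON-Lines I/O and the original-post filter.

A corpus is a pair of JSON-Lines files: one tweet object per line in
``tweets.jsonl`` and one user (author profile) object per line in
``users.jsonl``.  Hashtags arrive pre-extracted, the way platform entity
metadata delivers them (no leading ``#``); a regex fallback recovers tags
from raw text for records that lack the field.  Retweets are carried with a
flag and dropped by :func:`filter_original_posts` so that every analysis
downstream sees original posts only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator

from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .errors import CorpusParseError, ReferentialIntegrityError

__all__ = [
    "TweetRecord",
    "UserRecord",
    "Corpus",
    "extract_hashtags_from_text",
    "read_corpus",
    "write_corpus",
    "filter_original_posts",
]

_HASHTAG_RE = re.compile(r"#(\w+)")


def extract_hashtags_from_text(text: str) -> list[str]:
    """Fallback hashtag parser: ``#`` followed by word characters.

    Used only for records whose ``hashtags`` field is absent; entity
    metadata, when present, is authoritative.
    """
    return _HASHTAG_RE.findall(text)


class TweetRecord(BaseModel):
    """One original-or-retweet post.

    ``hashtags`` entries are stored as delivered (case preserved, no ``#``);
    normalization is the affinity-space layer's job.  ``created_at`` must be
    an ISO-8601 instant and is coerced to UTC.
    """

    model_config = ConfigDict(extra="ignore", frozen=True)

    tweet_id: str
    author_id: str
    created_at: datetime
    text: str = ""
    hashtags: tuple[str, ...] = ()
    urls: tuple[str, ...] = ()
    is_retweet: bool = False

    @field_validator("tweet_id", "author_id")
    @classmethod
    def _nonempty_id(cls, v: str) -> str:
        if not v:
            raise ValueError("identifier must be non-empty")
        return v

    @field_validator("created_at")
    @classmethod
    def _utc(cls, v: datetime) -> datetime:
        if v.tzinfo is None:
            raise ValueError("created_at must carry an explicit UTC offset")
        return v.astimezone(timezone.utc)

    @field_validator("hashtags")
    @classmethod
    def _clean_tags(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        for tag in v:
            if not tag or "#" in tag or any(c.isspace() for c in tag):
                raise ValueError(f"malformed hashtag entry {tag!r}")
        return v


class UserRecord(BaseModel):
    """One account profile: opaque id, display name, biography text."""

    model_config = ConfigDict(extra="ignore", frozen=True)

    user_id: str
    name: str = ""
    description: str = ""

    @field_validator("user_id")
    @classmethod
    def _nonempty_id(cls, v: str) -> str:
        if not v:
            raise ValueError("user_id must be non-empty")
        return v


@dataclass
class Corpus:
    """A validated collection of tweets plus the profiles of their authors.

    Invariants checked on construction: tweet and user ids are unique, and
    every tweet's ``author_id`` resolves to exactly one user record.
    """

    tweets: list[TweetRecord]
    users: list[UserRecord]
    users_by_id: dict[str, UserRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen_tweets: set[str] = set()
        for t in self.tweets:
            if t.tweet_id in seen_tweets:
                raise ValueError(f"duplicate tweet_id {t.tweet_id!r}")
            seen_tweets.add(t.tweet_id)
        self.users_by_id = {}
        for u in self.users:
            if u.user_id in self.users_by_id:
                raise ValueError(f"duplicate user_id {u.user_id!r}")
            self.users_by_id[u.user_id] = u
        missing = {t.author_id for t in self.tweets} - self.users_by_id.keys()
        if missing:
            raise ReferentialIntegrityError(
                f"{len(missing)} author_id(s) without a user record, "
                f"e.g. {sorted(missing)[:3]}"
            )

    def __len__(self) -> int:
        return len(self.tweets)

    @property
    def window(self) -> tuple[datetime, datetime]:
        """Min/max tweet timestamps — the observed collection window."""
        stamps = [t.created_at for t in self.tweets]
        return min(stamps), max(stamps)


def _read_jsonl(path: str | Path, model: type[BaseModel]) -> Iterator[BaseModel]:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(str(path), line_no, f"invalid JSON: {exc.msg}") from exc
            if "hashtags" not in obj and model is TweetRecord and "text" in obj:
                obj["hashtags"] = extract_hashtags_from_text(obj["text"])
            try:
                yield model.model_validate(obj)
            except ValidationError as exc:
                first = exc.errors()[0]
                loc = ".".join(str(p) for p in first["loc"]) or "<record>"
                raise CorpusParseError(
                    str(path), line_no, f"{loc}: {first['msg']}"
                ) from exc


def read_corpus(tweets_path: str | Path, users_path: str | Path) -> Corpus:
    """Read and validate a corpus from its two JSON-Lines files.

    Unknown extra fields on either record type are ignored.  Raises
    :class:`CorpusParseError` (naming file and line) for malformed records
    and :class:`ReferentialIntegrityError` for tweets whose author has no
    profile record.
    """
    tweets = list(_read_jsonl(tweets_path, TweetRecord))
    users = list(_read_jsonl(users_path, UserRecord))
    return Corpus(tweets=tweets, users=users)


def write_corpus(corpus: Corpus, tweets_path: str | Path, users_path: str | Path) -> None:
    """Write a corpus to JSON-Lines with sorted keys (byte-stable output)."""
    _dump(corpus.tweets, tweets_path)
    _dump(corpus.users, users_path)


def _dump(records: Iterable[BaseModel], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            payload = rec.model_dump(mode="json")
            fh.write(json.dumps(payload, sort_keys=True, ensure_ascii=False))
            fh.write("\n")


def filter_original_posts(corpus: Corpus) -> Corpus:
    """Drop retweets, keeping every user record.

    Idempotent; the result contains exactly the tweets with
    ``is_retweet == False``.
    """
    return Corpus(
        tweets=[t for t in corpus.tweets if not t.is_retweet],
        users=list(corpus.users),
    )
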