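"""High-recall candidate retrieval.

Retweets and "reported speech" (quoted text, headline-style attributions) are
excluded, then a versioned table of query patterns flags tweets that
potentially mention a user age between 10 and 99. Retrieval is deliberately
noisy-but-complete: distinguishing genuine self-reports from the rest is the
classifier's job downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .textprep import normalize_unicode_punct, preprocess_for_retrieval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawTweet:
    """One tweet record: identity, author, UTC timestamp, text."""

    tweet_id: str
    user_id: str
    created_at: datetime
    text: str
    retweeted: bool = False  # optional retweet flag from the source record

    def __post_init__(self) -> None:
        if not self.tweet_id:
            raise ValueError("tweet_id must be nonempty")


@dataclass(frozen=True)
class QueryPattern:
    pattern_id: str
    expression: str
    description: str = ""

    def __post_init__(self) -> None:
        re.compile(self.expression)  # must compile

    @property
    def pattern(self) -> re.Pattern:
        return re.compile(self.expression)


@dataclass(frozen=True)
class CandidateTweet:
    """A tweet that survived both filters and matched >=1 query pattern."""

    tweet: RawTweet
    matched_pattern_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.matched_pattern_ids:
            raise ValueError("matched_pattern_ids must be nonempty")


_RT_RE = re.compile(r"^\s*rt\s+@", re.IGNORECASE)

# A two-digit number bounded on both sides (the age range retrieval cares about).
_AGE_DIGITS_RE = re.compile(r"(?<!\d)[1-9]\d(?!\d)")

#: Headline / attribution heuristics standing in for a full reported-speech
#: detector. A tweet is treated as reported speech when an age-like number
#: falls inside paired double quotes, or when any of these fire.
HEADLINE_PATTERNS: tuple[str, ...] = (
    r"-\s*via\s+\S+",                      # "... — via NewsSite" (dash normalized)
    r"\bvia\s+@\w+",                       # "via @outlet"
    r"^[^,]{1,40},\s*[1-9]\d,\s*(?:arrested|charged|dies|died|dead|found|missing|killed|sentenced|wins|rescued)\b",
    r"^\s*\w+(?:\s+\w+){0,2}\s+says\s*:",  # leading "Outlet says:"
)
_HEADLINE_RES = tuple(re.compile(p, re.IGNORECASE) for p in HEADLINE_PATTERNS)

_QUOTED_RE = re.compile(r'"([^"]*)"')


def is_retweet(tweet: RawTweet) -> bool:
    """True iff the record is flagged as a retweet or starts with 'RT @'."""
    return tweet.retweeted or bool(_RT_RE.match(tweet.text))


def is_reported_speech(tweet: RawTweet) -> bool:
    """True iff an age-like number sits inside paired quotation marks, or the
    text matches one of the declared headline heuristics."""
    text = normalize_unicode_punct(tweet.text)
    for quoted in _QUOTED_RE.findall(text):
        if _AGE_DIGITS_RE.search(quoted):
            return True
    return any(rx.search(text) for rx in _HEADLINE_RES)


def load_patterns(path: Optional[str | Path] = None) -> list[QueryPattern]:
    """Load the query-pattern table (tab-separated, '#' comments); the
    packaged default set is used when no path is given."""
    if path is None:
        text = (resources.files("tweetage") / "data" / "patterns.tsv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    patterns: list[QueryPattern] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"patterns line {lineno}: expected >=2 tab-separated fields")
        patterns.append(QueryPattern(parts[0], parts[1], parts[2] if len(parts) > 2 else ""))
    if not patterns:
        raise ValueError("empty pattern table")
    return patterns


def match_patterns(text: str, patterns: Sequence[QueryPattern]) -> tuple[str, ...]:
    """Pattern ids matching the retrieval-normalized text."""
    normalized = preprocess_for_retrieval(text).normalized
    return tuple(p.pattern_id for p in patterns if p.pattern.search(normalized))


def match_candidates(
    tweets: Iterable[RawTweet],
    patterns: Optional[Sequence[QueryPattern]] = None,
) -> Iterator[CandidateTweet]:
    """Yield, in input order, tweets that pass both filters and match at
    least one query pattern. Malformed records are logged and skipped; the
    stream never aborts."""
    if patterns is None:
        patterns = load_patterns()
    for tweet in tweets:
        try:
            if is_retweet(tweet) or is_reported_speech(tweet):
                continue
            matched = match_patterns(tweet.text, patterns)
        except Exception:  # pragma: no cover - defensive: keep the stream alive
            log.exception("skipping malformed tweet record: %r", tweet)
            continue
        if matched:
            yield CandidateTweet(tweet, matched)
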