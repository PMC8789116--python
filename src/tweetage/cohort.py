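"""User-level aggregation of tweet-level age predictions.

A user may self-report an age in several tweets over time. One tweet per
user is selected uniformly at random (seeded); for users with multiple
age-predicted tweets a timeline-consistency flag records whether the span
between posting dates agrees, within one year, with the span between the
minimum and maximum extracted ages. Final ages are binned into the age
groups 10-17, 18-29, 30-49, 50-64 and 65-99 (the sub-adult bin is kept so
no extracted age is silently dropped).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Optional, Sequence

#: (label, low, high) inclusive age-group bins.
AGE_GROUPS: tuple[tuple[str, int, int], ...] = (
    ("10-17", 10, 17),
    ("18-29", 18, 29),
    ("30-49", 30, 49),
    ("50-64", 50, 64),
    ("65-99", 65, 99),
)

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class AgedTweet:
    """A tweet-level age prediction joined with its author and timestamp."""

    user_id: str
    tweet_id: str
    created_at: datetime
    age: int


@dataclass(frozen=True)
class UserAgeRecord:
    user_id: str
    selected_tweet_id: str
    age: int
    n_age_tweets: int
    consistent: Optional[bool] = None  # defined iff n_age_tweets >= 2

    def __post_init__(self) -> None:
        if not 10 <= self.age <= 99:
            raise ValueError("age must be in [10, 99]")
        if self.n_age_tweets < 1:
            raise ValueError("n_age_tweets must be >= 1")


def years_between(earliest: datetime, latest: datetime) -> int:
    """Elapsed fractional years truncated to whole years."""
    return int(abs((latest - earliest).total_seconds()) / (86400 * _DAYS_PER_YEAR))


def timeline_consistency(predictions: Sequence[AgedTweet]) -> bool:
    """True iff the posting-date span agrees with the extracted-age span to
    within one year. Requires >=2 predictions for one user."""
    if len(predictions) < 2:
        raise ValueError("timeline consistency needs >=2 predictions")
    dates = [p.created_at for p in predictions]
    ages = [p.age for p in predictions]
    return abs(years_between(min(dates), max(dates)) - (max(ages) - min(ages))) <= 1


def select_user_age(predictions: Iterable[AgedTweet], seed: int) -> list[UserAgeRecord]:
    """One record per user, the source tweet drawn uniformly per user.

    Selection is reproducible given the seed and independent of input order
    (users and their tweets are processed in sorted order).
    """
    by_user: dict[str, list[AgedTweet]] = {}
    for p in predictions:
        by_user.setdefault(p.user_id, []).append(p)
    rng = random.Random(seed)
    records: list[UserAgeRecord] = []
    for user_id in sorted(by_user):
        group = sorted(by_user[user_id], key=lambda p: p.tweet_id)
        pick = rng.choice(group)
        consistent = timeline_consistency(group) if len(group) >= 2 else None
        records.append(
            UserAgeRecord(
                user_id=user_id,
                selected_tweet_id=pick.tweet_id,
                age=pick.age,
                n_age_tweets=len(group),
                consistent=consistent,
            )
        )
    return records


def age_group_histogram(records: Iterable[UserAgeRecord]) -> dict[str, int]:
    """Counts of users per age group; values always sum to len(records)."""
    counts = {label: 0 for label, _, _ in AGE_GROUPS}
    for rec in records:
        for label, low, high in AGE_GROUPS:
            if low <= rec.age <= high:
                counts[label] += 1
                break
    return counts
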