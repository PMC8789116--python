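"""Synthetic labeled tweet corpus with known ground-truth ages.

Templates emulate the linguistic structure the pipeline assumes: "age"
templates realize each arithmetic family the extractor implements (present
birthday, future offsets with unit conversion, past period plus past age,
two age mentions, repeated-birthday counts, ...) and carry a ground-truth
age computed by the same arithmetic; "no age" templates contain plausible
10-99 numbers that are temporally ambiguous, belong to another person, or
are not ages at all (prices, scores, follower counts).

The default class mix is 32% "age" / 68% "no age", matching the label
distribution the pipeline's classifier is tuned for. Generation is fully
reproducible: two runs with the same seed are byte-identical.

This generator makes no attempt at statistical fidelity to real Twitter
text; it is a controlled test bed with known answers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

from ._numwords import ordinal_suffix
from .classify import AGE, NO_AGE, LabeledTweet
from .extract import TimePeriod, period_to_years
from .retrieval import RawTweet


@dataclass(frozen=True)
class Template:
    """A surface form with slots {n}, {ord}, {n2}, {k}, {filler}.

    For "age" templates, ``arithmetic`` names the extraction-rule family the
    surface should trigger, and the ground-truth age is computed from the
    sampled slot values with that same arithmetic. ``unit`` fixes the time
    unit for period-based templates.
    """

    template_id: str
    label: str  # "age" | "no_age"
    surface: str
    arithmetic: Optional[str] = None  # age templates only
    unit: str = "years"


AGE_TEMPLATES: tuple[Template, ...] = (
    Template("its_my_bday", AGE, "It's my {n}{ord} birthday! {filler}", "direct"),
    Template("happy_to_me", AGE, "happy {n}{ord} birthday to me {filler}", "direct"),
    Template("excited_my_nth", AGE, "excited for my {n}{ord} {filler}", "minus_one"),
    Template("countdown_years", AGE, "{k} more years until my {n}{ord} birthday {filler}", "minus_period", "years"),
    Template("turning_in_weeks", AGE, "can't believe i'm turning {n} in {k} weeks {filler}", "minus_period", "weeks"),
    Template("ago_at_age", AGE, "started dancing {k} yrs ago at the age of {n} {filler}", "plus_period", "years"),
    Template("two_ages", AGE, "i started at {n} and i'm now at {n2} {filler}", "max_of_two"),
    Template("turned_times", AGE, "i've turned {n} {k} times now {filler}", "plus_repeats_minus_one"),
    Template("going_to_be", AGE, "can't believe i'm going to be {n} {filler}", "minus_one"),
    Template("turned_bare", AGE, "recently turned {n} and it feels weird {filler}", "direct"),
    Template("years_old", AGE, "i'm {n} years old {filler}", "direct"),
    Template("the_big", AGE, "celebrated the big {n} last weekend {filler}", "direct"),
    Template("at_age", AGE, "moved away at the age of {n} and never looked back {filler}", "direct"),
)

NO_AGE_TEMPLATES: tuple[Template, ...] = (
    Template("watch_me", NO_AGE, "i graduate in may only focusing on me watch me at {n} {filler}"),
    Template("had_turned", NO_AGE, "had just turned {n} then everything changed {k} weeks later {filler}"),
    Template("sister_bday", NO_AGE, "happy {n}{ord} birthday to my sister {filler}"),
    Template("brother_turns", NO_AGE, "my brother turns {n} today and i cannot believe it {filler}"),
    Template("price", NO_AGE, "this jersey cost {n} bucks what a steal {filler}"),
    Template("score", NO_AGE, "we lost the game {n} to {n2} absolutely heartbreaking {filler}"),
    Template("tickets", NO_AGE, "only {n} tickets left for the show tonight {filler}"),
    Template("followers", NO_AGE, "just hit {n} followers thank you all {filler}"),
)

DEFAULT_TEMPLATES: tuple[Template, ...] = AGE_TEMPLATES + NO_AGE_TEMPLATES

# Filler vocabulary deliberately avoids digits, number words and the trigger
# words of the extraction rules, so fillers never change the gold age.
_FILLER_WORDS = (
    "lol", "haha", "omg", "honestly", "so", "blessed", "grateful", "wild",
    "crazy", "mood", "vibes", "tbh", "fr", "deadass", "literally", "lowkey",
    "cannot", "even", "love", "life", "best", "ever", "feeling", "amazing",
    "wow", "yay", "finally", "excited", "nervous", "happy",
)
_HASHTAGS = ("#blessed", "#mood", "#fyp", "#tbt", "#grwm", "#nofilter")
_URLS = ("https://t.co/abc123", "https://pic.example/99x", "http://tinyurl.example/q7")


@dataclass(frozen=True)
class SynthTweet:
    tweet: RawTweet
    label: str
    gold_age: Optional[int]
    template_id: str

    def __post_init__(self) -> None:
        if self.gold_age is not None and not 10 <= self.gold_age <= 99:
            raise ValueError("gold_age must be in [10, 99]")


def as_labeled(st: SynthTweet) -> LabeledTweet:
    return LabeledTweet(tweet=st.tweet, label=st.label, gold_age=st.gold_age)


def _gold_age(t: Template, n: int, n2: int, k: int) -> int:
    op = t.arithmetic
    if op == "direct":
        return n
    if op == "minus_one":
        return n - 1
    if op == "max_of_two":
        return max(n, n2)
    if op == "plus_repeats_minus_one":
        return n + (k - 1)
    years = period_to_years(TimePeriod(k, t.unit))
    if op == "minus_period":
        return n - years
    if op == "plus_period":
        return years + n
    raise ValueError(f"template {t.template_id}: unknown arithmetic {op!r}")


def _sample_slots(t: Template, rng: random.Random) -> dict:
    # Slot ranges keep every computed gold age inside [10, 99].
    if t.arithmetic == "minus_period" and t.unit == "years":
        k = rng.randint(1, 5)
        n = rng.randint(10 + k, 99)
    elif t.arithmetic == "minus_period":
        k = rng.randint(1, 51)
        n = rng.randint(11, 99)
    elif t.arithmetic == "plus_period":
        k = rng.randint(1, 30)
        n = rng.randint(10, 99 - k)
    elif t.arithmetic == "plus_repeats_minus_one":
        k = rng.randint(2, 4)
        n = rng.randint(10, 99 - (k - 1))
    elif t.arithmetic == "minus_one":
        k = 0
        n = rng.randint(11, 99)
    else:  # direct, max_of_two, and all no_age templates
        k = rng.randint(1, 9)
        n = rng.randint(10, 99)
    n2 = rng.randint(10, 99)
    return {"n": n, "ord": ordinal_suffix(n), "n2": n2, "k": k}


def _filler(rng: random.Random, hashtag_rate: float, url_rate: float) -> str:
    parts = rng.sample(_FILLER_WORDS, rng.randint(1, 4))
    if rng.random() < hashtag_rate:
        parts.append(rng.choice(_HASHTAGS))
    if rng.random() < url_rate:
        parts.append(rng.choice(_URLS))
    return " ".join(parts)


def generate_corpus(
    n: int,
    age_fraction: float = 0.32,
    seed: int = 0,
    templates: Sequence[Template] = DEFAULT_TEMPLATES,
    hashtag_rate: float = 0.3,
    url_rate: float = 0.1,
    start: datetime = datetime(2018, 1, 1, tzinfo=timezone.utc),
    window_days: int = 365,
    users: Optional[int] = None,
) -> list[SynthTweet]:
    """Generate ``n`` labeled tweets with an ~``age_fraction`` "age" share.

    ``users`` caps the author pool (defaults to one author per tweet).
    Fully reproducible given the seed.
    """
    if not 0 < age_fraction < 1:
        raise ValueError("age_fraction must be in (0, 1)")
    age_templates = [t for t in templates if t.label == AGE]
    no_age_templates = [t for t in templates if t.label == NO_AGE]
    if n > 0 and (not age_templates or not no_age_templates):
        raise ValueError("templates must cover both classes")
    rng = random.Random(seed)
    n_users = users if users is not None else n
    tweets: list[SynthTweet] = []
    for i in range(n):
        is_age = rng.random() < age_fraction
        t = rng.choice(age_templates if is_age else no_age_templates)
        slots = _sample_slots(t, rng)
        text = t.surface.format(filler=_filler(rng, hashtag_rate, url_rate), **slots)
        gold = _gold_age(t, slots["n"], slots["n2"], slots["k"]) if is_age else None
        created = start + timedelta(seconds=rng.randrange(window_days * 86400))
        raw = RawTweet(
            tweet_id=f"t{i:07d}",
            user_id=f"u{rng.randrange(max(n_users, 1)):06d}",
            created_at=created,
            text=text,
        )
        tweets.append(SynthTweet(raw, t.label, gold, t.template_id))
    return tweets


def generate_rater_matrix(
    items: int, raters: int, accuracy: float, seed: int, age_fraction: float = 0.5
) -> tuple[list[list[int]], list[int]]:
    """Simulated annotation: each rater reports the gold binary label with
    probability ``accuracy``, else the flipped label. Returns (items x raters
    matrix, gold labels)."""
    if not 0.5 <= accuracy <= 1:
        raise ValueError("accuracy must be in [0.5, 1]")
    rng = random.Random(seed)
    gold = [int(rng.random() < age_fraction) for _ in range(items)]
    matrix = [
        [g if rng.random() < accuracy else 1 - g for _ in range(raters)]
        for g in gold
    ]
    return matrix, gold
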