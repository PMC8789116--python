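"""Rule-based exact-age extraction.

The extractor runs an ordered table of linguistic patterns over the
extraction-normalized tweet text. Each pattern captures one or two digit
groups (and optionally a unit of time) and is bound to a small arithmetic
rule that converts the captures into an age in whole years:

========================  ====================================================
arithmetic                age
========================  ====================================================
direct                    N                  ("recently turned 47" -> 47)
minus_one                 N - 1              ("tomorrow i'll be 20" -> 19)
minus_period              N - years(k,unit)  ("turning 18 in 3 weeks" -> 17)
plus_period               years(k,unit) + N  ("20 yrs ago at the age of 19" -> 39)
max_of_two                max(N1, N2)        ("started at 28 ... at 35" -> 35)
plus_repeats_minus_one    N + (k - 1)        ("turned 21 three times" -> 23)
========================  ====================================================

Sub-year periods are converted to years by ceiling division (3 weeks -> 1
year). Rules are tried strictly in ascending ``order_index``; the first match
wins. If no rule matches, the fallback extracts the first standalone
two-digit group. Results outside the supported 10-99 range are discarded
(reported as no age found) rather than clamped: retrieval already restricts
candidate ages to 10-99, so out-of-range arithmetic signals a mis-match.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .textprep import preprocess_for_extraction

log = logging.getLogger(__name__)

AGE_MIN = 10
AGE_MAX = 99

ARITHMETIC_OPS = frozenset(
    {
        "direct",
        "minus_one",
        "minus_period",
        "plus_period",
        "max_of_two",
        "plus_repeats_minus_one",
        "fallback_first_group",
    }
)
_NEEDS_PERIOD = frozenset({"minus_period", "plus_period", "plus_repeats_minus_one"})

_UNIT_DIVISOR = {"years": 1, "months": 12, "weeks": 52, "days": 365}

FALLBACK_RULE_ID = "fallback"
_FALLBACK_RE = re.compile(r"(?<!\d)(\d\d)(?!\d)")


@dataclass(frozen=True)
class TimePeriod:
    """A nonnegative time span with a calendar unit."""

    magnitude: int
    unit: str  # years | months | weeks | days

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("period magnitude must be nonnegative")
        if self.unit not in _UNIT_DIVISOR:
            raise ValueError(f"unknown time unit: {self.unit!r}")


@dataclass(frozen=True)
class ExtractionRule:
    rule_id: str
    order_index: int
    expression: str
    arithmetic: str
    period_source: str = "none"  # n1 | n2 | none — which capture is the period

    def __post_init__(self) -> None:
        if self.arithmetic not in ARITHMETIC_OPS:
            raise ValueError(f"unknown arithmetic {self.arithmetic!r}")
        compiled = re.compile(self.expression)
        groups = compiled.groupindex
        if "n" not in groups:
            raise ValueError(f"rule {self.rule_id}: missing capture 'n'")
        if self.arithmetic in _NEEDS_PERIOD and "k" not in groups:
            raise ValueError(f"rule {self.rule_id}: arithmetic needs capture 'k'")
        if self.arithmetic == "max_of_two" and "n2" not in groups:
            raise ValueError(f"rule {self.rule_id}: max_of_two needs capture 'n2'")

    @property
    def pattern(self) -> re.Pattern:
        return re.compile(self.expression)


@dataclass(frozen=True)
class AgePrediction:
    """An extracted exact age with its provenance."""

    tweet_id: str
    age: int
    rule_id: str
    matched_span: tuple[int, int]  # over the extraction-normalized text


def period_to_years(p: TimePeriod) -> int:
    """Convert a time period to whole years, rounding sub-year units up.

    3 weeks -> 1 year, 13 months -> 2 years, 0 of anything -> 0.
    """
    d = _UNIT_DIVISOR[p.unit]
    return -(-p.magnitude // d)


def normalize_unit(raw: Optional[str]) -> str:
    """Map a captured unit token ('yrs', 'mos', 'week', ...) to its canonical
    unit name; absent captures default to years."""
    if raw is None:
        return "years"
    u = raw.lower()
    if u.startswith("y"):
        return "years"
    if u.startswith("mo"):
        return "months"
    if u.startswith("w"):
        return "weeks"
    if u.startswith("d"):
        return "days"
    raise ValueError(f"unrecognized time unit: {raw!r}")


def apply_rule(rule: ExtractionRule, captures: Mapping[str, Optional[str]]) -> int:
    """Apply a rule's arithmetic to its captured digit groups.

    Returns the computed age in years (which may fall outside 10-99; the
    caller range-checks). ``captures`` is a mapping of named groups from the
    rule's expression.
    """
    n = int(captures["n"])
    op = rule.arithmetic
    if op == "direct":
        return n
    if op == "minus_one":
        return n - 1
    if op == "fallback_first_group":
        return n
    if op == "max_of_two":
        return max(n, int(captures["n2"]))  # type: ignore[arg-type]
    k = int(captures["k"])  # type: ignore[arg-type]
    if op == "plus_repeats_minus_one":
        return n + (k - 1)
    period = TimePeriod(k, normalize_unit(captures.get("unit")))
    if op == "minus_period":
        return n - period_to_years(period)
    if op == "plus_period":
        return period_to_years(period) + n
    raise AssertionError(op)


def load_rules(path: Optional[str | Path] = None) -> list[ExtractionRule]:
    """Load the ordered rule table (tab-separated, '#' comments).

    With no path, the packaged default table is used.
    """
    if path is None:
        text = (resources.files("tweetage") / "data" / "rules.tsv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    rules: list[ExtractionRule] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"rules line {lineno}: expected 5 tab-separated fields")
        order_s, rule_id, arithmetic, period_source, expression = parts
        rules.append(
            ExtractionRule(
                rule_id=rule_id,
                order_index=int(order_s),
                expression=expression,
                arithmetic=arithmetic,
                period_source=period_source,
            )
        )
    orders = [r.order_index for r in rules]
    if len(set(orders)) != len(orders):
        raise ValueError("duplicate order_index in rule table")
    return sorted(rules, key=lambda r: r.order_index)


def extract_age(
    text: str,
    rules: Optional[Sequence[ExtractionRule]] = None,
    tweet_id: str = "",
) -> Optional[AgePrediction]:
    """Extract the exact age self-reported in a tweet, or None.

    The text is normalized (spelled numbers to digits, URLs/usernames
    removed, digit groups fused), then rules are tried strictly in order; the
    first matching rule's arithmetic is applied. If no rule matches, the
    first standalone two-digit group is taken verbatim.
    """
    if rules is None:
        rules = _default_rules()
    normalized = preprocess_for_extraction(text).normalized
    for rule in rules:
        m = rule.pattern.search(normalized)
        if m is None:
            continue
        age = apply_rule(rule, m.groupdict())
        if AGE_MIN <= age <= AGE_MAX:
            return AgePrediction(tweet_id, age, rule.rule_id, m.span())
        log.info(
            "rule %s produced out-of-range age %d for tweet %s; no age emitted",
            rule.rule_id, age, tweet_id,
        )
        return None
    m = _FALLBACK_RE.search(normalized)
    if m is None:
        return None
    age = int(m.group(1))
    if not AGE_MIN <= age <= AGE_MAX:
        return None
    return AgePrediction(tweet_id, age, FALLBACK_RULE_ID, m.span())


_RULES_CACHE: Optional[list[ExtractionRule]] = None


def _default_rules() -> list[ExtractionRule]:
    global _RULES_CACHE
    if _RULES_CACHE is None:
        _RULES_CACHE = load_rules()
    return _RULES_CACHE


@dataclass(frozen=True)
class OrderViolation:
    text: str
    expected_rule_id: str
    actual_rule_id: Optional[str]


def validate_rule_order(
    rules: Sequence[ExtractionRule],
    probes: Iterable[tuple[str, str]],
) -> list[OrderViolation]:
    """Check that each probe text matches its expected rule first.

    Returns the list of violations (empty means the ordering is consistent
    with the probes). Raises on an empty probe list, which would vacuously
    pass.
    """
    probes = list(probes)
    if not probes:
        raise ValueError("probe list must be nonempty")
    violations: list[OrderViolation] = []
    for text, expected in probes:
        pred = extract_age(text, rules)
        actual = pred.rule_id if pred is not None else None
        if actual != expected:
            violations.append(OrderViolation(text, expected, actual))
    return violations
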