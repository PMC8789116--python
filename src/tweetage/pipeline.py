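"""End-to-end orchestration: retrieval -> classification -> extraction.

Tweets flow through the stages in order; a tweet dropped by one stage never
reaches the next, so the stage counts form a monotone funnel. Classification
can be wired either to a trained model or to gold labels (for evaluating the
extractor in isolation). Every run returns a :class:`StageReport` with the
per-stage accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from . import classify as _classify
from .cohort import AgedTweet
from .extract import ExtractionRule, extract_age, load_rules
from .retrieval import QueryPattern, RawTweet, load_patterns, match_candidates

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PredictionRecord:
    """Tweet-level output: extracted age joined with tweet identity/metadata."""

    tweet_id: str
    user_id: str
    created_at: datetime
    age: int
    rule_id: str
    matched_span: tuple[int, int]

    def as_aged_tweet(self) -> AgedTweet:
        return AgedTweet(self.user_id, self.tweet_id, self.created_at, self.age)


@dataclass
class StageReport:
    """Counts of tweets surviving each stage (a monotone funnel)."""

    n_input: int = 0
    n_candidates: int = 0
    n_classified_age: int = 0
    n_predictions: int = 0
    skipped_reasons: dict[str, int] = field(default_factory=dict)

    def note_skip(self, reason: str) -> None:
        self.skipped_reasons[reason] = self.skipped_reasons.get(reason, 0) + 1


@dataclass
class PipelineConfig:
    """File-based configuration; round-trips losslessly through JSON."""

    pattern_file: Optional[str] = None  # None -> packaged defaults
    rule_file: Optional[str] = None
    model_file: Optional[str] = None
    seed: int = 0
    input_format: str = "jsonl"
    candidates_path: Optional[str] = None  # materialize intermediates when set
    predictions_path: Optional[str] = None

    def to_file(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.__dict__, indent=2), encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import json

        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def validate(self) -> None:
        for name in ("pattern_file", "rule_file", "model_file"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} does not exist: {value}")


def run_pipeline(
    tweets: Iterable[RawTweet],
    patterns: Optional[Sequence[QueryPattern]] = None,
    rules: Optional[Sequence[ExtractionRule]] = None,
    classifier=None,
    gold_labels: Optional[Mapping[str, str]] = None,
) -> tuple[list[PredictionRecord], StageReport]:
    """Run retrieval, classification and extraction in order.

    Classification uses the trained ``classifier`` model when given,
    otherwise the ``gold_labels`` mapping (tweet_id -> "age"/"no_age"); with
    neither, every candidate is treated as "age" (retrieval + extraction
    only). Tweets classified "no_age" are never passed to extraction.
    """
    report = StageReport()
    tweets = list(tweets)
    report.n_input = len(tweets)

    try:
        if patterns is None:
            patterns = load_patterns()
        candidates = list(match_candidates(tweets, patterns))
    except Exception as exc:
        raise PipelineError("retrieval", str(exc)) from exc
    report.n_candidates = len(candidates)

    try:
        if classifier is not None:
            labels = _classify.predict(classifier, candidates)
        elif gold_labels is not None:
            labels = [gold_labels.get(c.tweet.tweet_id, _classify.NO_AGE) for c in candidates]
        else:
            labels = [_classify.AGE] * len(candidates)
    except Exception as exc:
        raise PipelineError("classification", str(exc)) from exc
    age_tweets = [c for c, lab in zip(candidates, labels) if lab == _classify.AGE]
    report.n_classified_age = len(age_tweets)

    try:
        if rules is None:
            rules = load_rules()
        records: list[PredictionRecord] = []
        for c in age_tweets:
            pred = extract_age(c.tweet.text, rules, tweet_id=c.tweet.tweet_id)
            if pred is None:
                report.note_skip("no_age_extracted")
                continue
            records.append(
                PredictionRecord(
                    tweet_id=c.tweet.tweet_id,
                    user_id=c.tweet.user_id,
                    created_at=c.tweet.created_at,
                    age=pred.age,
                    rule_id=pred.rule_id,
                    matched_span=pred.matched_span,
                )
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("extraction", str(exc)) from exc
    report.n_predictions = len(records)
    return records, report
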