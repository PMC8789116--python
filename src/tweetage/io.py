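"""Reading and writing the pipeline's on-disk formats.

Tweets travel as JSONL (one object per line: ``tweet_id``, ``user_id``,
``created_at`` ISO-8601, ``text``, optional ``retweeted``) or 4-column TSV.
Labeled corpora add ``label`` and optional ``gold_age``/``template_id``.
Intermediate artifacts (candidates, predictions) are always JSONL so any
stage can be run and audited in isolation. Malformed lines are logged with
their line number, counted, and skipped — a bad record never aborts a run.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional

import joblib

from .classify import ClassifierModel, LabeledTweet
from .retrieval import CandidateTweet, RawTweet
from .synthgen import SynthTweet

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class ReadReport:
    """Per-file accounting of skipped lines: (line number, reason)."""

    n_read: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _parse_timestamp(value: str) -> datetime:
    return datetime.fromisoformat(value.replace("Z", "+00:00"))


def _tweet_from_obj(obj: dict) -> RawTweet:
    return RawTweet(
        tweet_id=str(obj["tweet_id"]),
        user_id=str(obj["user_id"]),
        created_at=_parse_timestamp(obj["created_at"]),
        text=obj["text"],
        retweeted=bool(obj.get("retweeted", False)),
    )


def read_tweets(
    path: str | Path, fmt: str = "jsonl", report: Optional[ReadReport] = None
) -> list[RawTweet]:
    """Read tweets from JSONL or TSV; malformed lines are logged and skipped."""
    if fmt not in ("jsonl", "tsv"):
        raise ValueError(f"format must be 'jsonl' or 'tsv', got {fmt!r}")
    report = report if report is not None else ReadReport()
    tweets: list[RawTweet] = []
    with open(path, encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            rows: Iterable = ((i, line) for i, line in enumerate(fh, 1) if line.strip())
            for lineno, line in rows:
                try:
                    tweets.append(_tweet_from_obj(json.loads(line)))
                except (ValueError, KeyError, TypeError) as exc:
                    log.warning("%s line %d skipped: %s", path, lineno, exc)
                    report.skipped.append((lineno, str(exc)))
        else:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
                if not row:
                    continue
                try:
                    if len(row) < 4:
                        raise ValueError("expected 4 tab-separated columns")
                    tweets.append(
                        RawTweet(row[0], row[1], _parse_timestamp(row[2]), row[3])
                    )
                except ValueError as exc:
                    log.warning("%s line %d skipped: %s", path, lineno, exc)
                    report.skipped.append((lineno, str(exc)))
    report.n_read = len(tweets)
    return tweets


def _tweet_to_obj(t: RawTweet) -> dict:
    obj = {
        "tweet_id": t.tweet_id,
        "user_id": t.user_id,
        "created_at": t.created_at.isoformat(),
        "text": t.text,
    }
    if t.retweeted:
        obj["retweeted"] = True
    return obj


def write_tweets(tweets: Iterable[RawTweet], path: str | Path, fmt: str = "jsonl") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for t in tweets:
                fh.write(json.dumps(_tweet_to_obj(t), ensure_ascii=False) + "\n")
        elif fmt == "tsv":
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for t in tweets:
                writer.writerow([t.tweet_id, t.user_id, t.created_at.isoformat(), t.text])
        else:
            raise ValueError(f"format must be 'jsonl' or 'tsv', got {fmt!r}")


def write_synth(tweets: Iterable[SynthTweet], path: str | Path) -> None:
    """Synthetic corpus as JSONL with gold label/age/template fields."""
    with open(path, "w", encoding="utf-8") as fh:
        for st in tweets:
            obj = _tweet_to_obj(st.tweet)
            obj["label"] = st.label
            if st.gold_age is not None:
                obj["gold_age"] = st.gold_age
            obj["template_id"] = st.template_id
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_labeled(path: str | Path, report: Optional[ReadReport] = None) -> list[LabeledTweet]:
    """Read a labeled corpus (JSONL with 'label' and optional 'gold_age')."""
    report = report if report is not None else ReadReport()
    out: list[LabeledTweet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                out.append(
                    LabeledTweet(
                        tweet=_tweet_from_obj(obj),
                        label=obj["label"],
                        gold_age=obj.get("gold_age"),
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                log.warning("%s line %d skipped: %s", path, lineno, exc)
                report.skipped.append((lineno, str(exc)))
    report.n_read = len(out)
    return out


def write_candidates(candidates: Iterable[CandidateTweet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in candidates:
            obj = _tweet_to_obj(c.tweet)
            obj["matched_pattern_ids"] = list(c.matched_pattern_ids)
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_candidates(path: str | Path) -> list[CandidateTweet]:
    out: list[CandidateTweet] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                CandidateTweet(_tweet_from_obj(obj), tuple(obj["matched_pattern_ids"]))
            )
    return out


def write_predictions(records: Iterable, path: str | Path) -> None:
    """Write pipeline prediction records (dataclasses with tweet metadata and
    the extracted age) as JSONL."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "tweet_id": r.tweet_id,
                        "user_id": r.user_id,
                        "created_at": r.created_at.isoformat(),
                        "age": r.age,
                        "rule_id": r.rule_id,
                        "matched_span": list(r.matched_span),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def save_model(model: ClassifierModel, path: str | Path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path) -> ClassifierModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model archive version")
    return payload["model"]
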