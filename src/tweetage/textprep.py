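"""Text normalization transforms for retrieval, classification and extraction.

Each pipeline stage sees tweets through its own deterministic transform:

``retrieval``
    lowercasing, Unicode punctuation normalization and digit-group fusion, so
    high-recall query patterns can match forms like "the big 3-0".
``classifier_svm``
    placeholder normalization of URLs / @-usernames / digits, punctuation
    removal, lowercasing and Porter stemming — the bag-of-words view.
``classifier_neural``
    URL / @-username placeholders and lowercasing only; punctuation and
    digits are preserved for subword tokenizers.
``extraction``
    spelled-out numbers rewritten to digits, URLs and usernames deleted
    (they may contain digits), punctuation gaps between digit groups removed
    so split numbers fuse ("3-0" -> "30").

All transforms are idempotent: feeding a transform its own output returns the
same string.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Literal

from ._numwords import rewrite_spelled_numbers
from ._porter import stem

TransformId = Literal["retrieval", "classifier_svm", "classifier_neural", "extraction"]

#: Placeholder token spellings (fixed constants; any deterministic choice works).
URL_TOKEN = "<url>"
USER_TOKEN = "<user>"
DIGIT_TOKEN = "<d>"

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
# A gap between two digits is fused only if it contains at least one
# punctuation character; whitespace-only gaps separate distinct numbers.
_DIGIT_GAP_RE = re.compile(r"(?<=\d)\s*[^\w\s]\W*(?=\d)")
_WS_RE = re.compile(r"\s+")

# Sentinels (private-use codepoints) protect placeholder tokens from the
# punctuation-removal pass, which keeps the transforms idempotent.
_SENTINELS = {URL_TOKEN: "\ue000", USER_TOKEN: "\ue001", DIGIT_TOKEN: "\ue002"}

_UNICODE_PUNCT = {
    "‐": "-", "‑": "-", "‒": "-", "–": "-",
    "—": "-", "―": "-", "−": "-",
    "‘": "'", "’": "'", "‚": "'", "′": "'",
    "“": '"', "”": '"', "„": '"', "″": '"',
    "…": "...",
}
_PUNCT_TABLE = str.maketrans(_UNICODE_PUNCT)


@dataclass(frozen=True)
class NormalizedText:
    """A tweet text together with its normalized form under one transform."""

    original: str
    normalized: str
    transform_id: TransformId


def normalize_unicode_punct(text: str) -> str:
    """Map typographic dashes/quotes/ellipses to their ASCII equivalents."""
    return unicodedata.normalize("NFC", text).translate(_PUNCT_TABLE)


def fuse_digit_groups(text: str) -> str:
    """Delete punctuation (and adjoining spaces) sandwiched between digits.

    "the big 3-0" -> "the big 30"; "2 21st" is left alone (whitespace-only
    gap), so spelled-number rewriting never merges adjacent numbers.
    """
    return _DIGIT_GAP_RE.sub("", text)


def _protect(text: str) -> str:
    for token, sentinel in _SENTINELS.items():
        text = text.replace(token, sentinel)
    return text


def _restore(text: str) -> str:
    for token, sentinel in _SENTINELS.items():
        text = text.replace(sentinel, token)
    return text


def preprocess_for_retrieval(text: str) -> NormalizedText:
    out = normalize_unicode_punct(text).lower()
    out = fuse_digit_groups(out)
    out = _WS_RE.sub(" ", out).strip()
    return NormalizedText(text, out, "retrieval")


def preprocess_for_svm(text: str) -> NormalizedText:
    """Bag-of-words normalization: URL/user/digit placeholders, punctuation
    stripped, lowercased, Porter-stemmed token by token."""
    out = normalize_unicode_punct(text)
    out = _protect(out)
    out = _URL_RE.sub(_SENTINELS[URL_TOKEN], out)
    out = _MENTION_RE.sub(_SENTINELS[USER_TOKEN], out)
    out = out.lower()
    out = re.sub(r"\d", _SENTINELS[DIGIT_TOKEN], out)
    # Non-alphanumeric characters are removed (not blanked): "I'm" -> "im".
    out = re.sub(r"[^a-z\s\ue000-\ue002]", "", out)
    tokens = [stem(t) for t in out.split()]
    return NormalizedText(text, _restore(" ".join(tokens)), "classifier_svm")


def preprocess_for_neural(text: str) -> NormalizedText:
    """URL/user placeholders and lowercasing only."""
    out = _protect(text)
    out = _URL_RE.sub(_SENTINELS[URL_TOKEN], out)
    out = _MENTION_RE.sub(_SENTINELS[USER_TOKEN], out)
    out = _restore(out.lower())
    return NormalizedText(text, out, "classifier_neural")


def preprocess_for_extraction(text: str) -> NormalizedText:
    """Normalization ahead of the rule-based age extractor.

    URLs and usernames are deleted outright because they can contain digits;
    digit groups split by punctuation are fused; spelled-out numbers become
    digits. Matching downstream is case-insensitive, so the text is lowercased.
    """
    out = normalize_unicode_punct(text)
    out = _URL_RE.sub(" ", out)
    out = _MENTION_RE.sub(" ", out)
    out = out.lower()
    out = rewrite_spelled_numbers(out)
    out = fuse_digit_groups(out)
    out = _WS_RE.sub(" ", out).strip()
    return NormalizedText(text, out, "extraction")


_TRANSFORMS = {
    "retrieval": preprocess_for_retrieval,
    "classifier_svm": preprocess_for_svm,
    "classifier_neural": preprocess_for_neural,
    "extraction": preprocess_for_extraction,
}


def normalize(text: str, transform_id: TransformId) -> NormalizedText:
    """Apply the named transform (selectable from config by name)."""
    try:
        fn = _TRANSFORMS[transform_id]
    except KeyError:
        raise ValueError(f"unknown transform: {transform_id!r}") from None
    return fn(text)
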