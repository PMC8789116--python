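"""Rewriting spelled-out English numbers (1-99) to digit strings.

Cardinals ("twenty one", "twenty-one") become plain digits ("21"); ordinals
("twenty-first", "twentieth") become digits plus the usual ordinal suffix
("21st", "20th") so that downstream patterns over "<digits><st|nd|rd|th>"
match spelled and numeric forms alike.
"""

from __future__ import annotations

import re

_UNITS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9,
}
_TEENS = {
    "ten": 10, "eleven": 11, "twelve": 12, "thirteen": 13, "fourteen": 14,
    "fifteen": 15, "sixteen": 16, "seventeen": 17, "eighteen": 18,
    "nineteen": 19,
}
_TENS = {
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50,
    "sixty": 60, "seventy": 70, "eighty": 80, "ninety": 90,
}
_ORD_UNITS = {
    "first": 1, "second": 2, "third": 3, "fourth": 4, "fifth": 5,
    "sixth": 6, "seventh": 7, "eighth": 8, "ninth": 9,
}
_ORD_TEENS = {
    "tenth": 10, "eleventh": 11, "twelfth": 12, "thirteenth": 13,
    "fourteenth": 14, "fifteenth": 15, "sixteenth": 16, "seventeenth": 17,
    "eighteenth": 18, "nineteenth": 19,
}
_ORD_TENS = {
    "twentieth": 20, "thirtieth": 30, "fortieth": 40, "fiftieth": 50,
    "sixtieth": 60, "seventieth": 70, "eightieth": 80, "ninetieth": 90,
}


def ordinal_suffix(n: int) -> str:
    if 10 <= n % 100 <= 19:
        return "th"
    return {1: "st", 2: "nd", 3: "rd"}.get(n % 10, "th")


def _alt(words) -> str:
    return "|".join(sorted(words, key=len, reverse=True))


# Longest forms first: compound ordinal, compound cardinal, then simple forms.
_PATTERN = re.compile(
    r"\b(?:"
    rf"(?P<ctens>{_alt(_TENS)})[\s-](?P<cordunit>{_alt(_ORD_UNITS)})"
    rf"|(?P<tens>{_alt(_TENS)})[\s-](?P<unit>{_alt(_UNITS)})"
    rf"|(?P<ordword>{_alt({**_ORD_TEENS, **_ORD_TENS, **_ORD_UNITS})})"
    rf"|(?P<cardword>{_alt({**_TEENS, **_TENS, **_UNITS})})"
    r")\b",
    re.IGNORECASE,
)


def _substitute(m: re.Match) -> str:
    if m.group("ctens") is not None:
        n = _TENS[m.group("ctens").lower()] + _ORD_UNITS[m.group("cordunit").lower()]
        return f"{n}{ordinal_suffix(n)}"
    if m.group("tens") is not None:
        return str(_TENS[m.group("tens").lower()] + _UNITS[m.group("unit").lower()])
    if m.group("ordword") is not None:
        w = m.group("ordword").lower()
        n = _ORD_TEENS.get(w) or _ORD_TENS.get(w) or _ORD_UNITS[w]
        return f"{n}{ordinal_suffix(n)}"
    w = m.group("cardword").lower()
    return str(_TEENS.get(w) or _TENS.get(w) or _UNITS[w])


def rewrite_spelled_numbers(text: str) -> str:
    """Replace spelled-out numbers 1-99 (cardinal and ordinal) with digits."""
    return _PATTERN.sub(_substitute, text)
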