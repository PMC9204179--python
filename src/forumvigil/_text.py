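"""Shared text-scanning, calendar-quarter, and rounding utilities.

Word boundaries throughout the package are transitions between alphanumeric
and non-alphanumeric characters; hyphens and apostrophes inside a phrase are
ordinary characters, so terms like "stevens-johnson syndrome" match as-is.
"""
from __future__ import annotations

import re
from datetime import datetime, timedelta, timezone
from decimal import ROUND_HALF_UP, Decimal

_ALNUM = "0-9A-Za-z"
_QUARTER_RE = re.compile(r"(\d{4})Q([1-4])")


def phrase_regex(phrase: str) -> re.Pattern[str]:
    """Compile a case-insensitive, word-boundary-anchored pattern for a phrase.

    Internal whitespace matches any run of whitespace.
    """
    body = re.escape(phrase.strip().lower())
    body = re.sub(r"\\[ ]", r"\\s+", body)
    return re.compile(
        rf"(?<![{_ALNUM}]){body}(?![{_ALNUM}])", re.IGNORECASE
    )


def contains_phrase(text: str, pattern: re.Pattern[str]) -> bool:
    return pattern.search(text) is not None


def tokenize(text: str) -> list[str]:
    """Lowercased alphanumeric word tokens."""
    return re.findall(rf"[{_ALNUM}]+", text.lower())


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (presentation rounding for all percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return v


# ---------------------------------------------------------------------------
# Calendar quarters: labels "YYYYQk", Jan-Mar = Q1, timestamps are UTC.
# ---------------------------------------------------------------------------

def parse_quarter(label: str) -> tuple[int, int]:
    m = _QUARTER_RE.fullmatch(label)
    if m is None:
        raise ValueError(f"not a quarter label (expected YYYYQk): {label!r}")
    return int(m.group(1)), int(m.group(2))


def quarter_label(ts: datetime) -> str:
    return f"{ts.year}Q{(ts.month - 1) // 3 + 1}"


def quarter_key(label: str) -> int:
    """Sortable integer key for a quarter label."""
    y, q = parse_quarter(label)
    return 4 * y + (q - 1)


def quarter_range(start: str, end: str) -> list[str]:
    """Inclusive list of quarter labels from start to end."""
    a, b = quarter_key(start), quarter_key(end)
    if b < a:
        raise ValueError(f"empty quarter range: {start}..{end}")
    return [f"{k // 4}Q{k % 4 + 1}" for k in range(a, b + 1)]


def quarter_bounds(label: str) -> tuple[datetime, datetime]:
    """[start, end) instants of a quarter in UTC."""
    y, q = parse_quarter(label)
    start = datetime(y, 3 * (q - 1) + 1, 1, tzinfo=timezone.utc)
    if q == 4:
        end = datetime(y + 1, 1, 1, tzinfo=timezone.utc)
    else:
        end = datetime(y, 3 * q + 1, 1, tzinfo=timezone.utc)
    return start, end


def quarter_end(label: str) -> datetime:
    """Last representable instant of a quarter (for cumulative slicing)."""
    return quarter_bounds(label)[1] - timedelta(microseconds=1)


def ensure_utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)
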