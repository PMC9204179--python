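"""Quarterly adverse-event frequency surfaces over drug-mentioning posts.

For a drug of interest, each calendar quarter contributes N_q (posts
mentioning the drug), n_q (posts mentioning the drug and a given PT, a post
counting at most once per PT), and f_q = 100*n_q/N_q.  The pseudo-PT
``ANY_AE`` counts posts with at least one mapped PT of any kind.  Storage is
full precision; presentation rounds half away from zero (one decimal for
ANY_AE percentages, three decimals for per-PT frequencies).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._text import quarter_key, quarter_label, quarter_range, round_half_away
from .ingest import CleanPost
from .terminology import MatchedEvent

ANY_AE = "ANY_AE"

#: cumulative-count gate below which a trend is not interpreted
DEFAULT_MIN_CUMULATIVE_COUNT = 50


@dataclass
class QuarterlySummary:
    """Per-quarter drug-post denominators and per-PT numerators for one drug."""

    drug: str
    quarters: list[str]                       # contiguous, ascending
    n_posts: dict[str, int]                   # quarter -> N_q
    pt_counts: dict[str, dict[str, int]]      # quarter -> {pt -> n_q}
    any_ae_counts: dict[str, int]             # quarter -> posts with >=1 PT

    @property
    def pt_codes(self) -> set[str]:
        out: set[str] = set()
        for counts in self.pt_counts.values():
            out.update(counts)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in self.quarters:
            for pt, n in sorted(self.pt_counts[q].items()):
                rows.append({"drug": self.drug, "quarter": q, "pt_code": pt, "n": n})
        return pd.DataFrame(rows, columns=["drug", "quarter", "pt_code", "n"])


def quarterly_summary(
    posts: Iterable[CleanPost],
    events: Iterable[MatchedEvent],
    drug: str,
    period: tuple[str, str] | None = None,
) -> QuarterlySummary:
    """Tally drug posts and deduplicated PT mentions by calendar quarter.

    Quarters with zero drug posts are present with N_q = 0.  The quarter span
    defaults to the full span of the input posts.
    """
    posts = list(posts)
    by_id = {p.post_id: p for p in posts}
    for e in events:
        if e.post_id not in by_id:
            raise ValueError(f"event references unknown post {e.post_id!r}")

    if period is None:
        if not posts:
            raise ValueError("no posts and no explicit period")
        labels = [quarter_label(p.timestamp) for p in posts]
        period = (min(labels, key=quarter_key), max(labels, key=quarter_key))
    quarters = quarter_range(*period)

    n_posts = {q: 0 for q in quarters}
    pt_counts: dict[str, dict[str, int]] = {q: {} for q in quarters}
    any_ae = {q: 0 for q in quarters}

    drug_posts = {p.post_id: p for p in posts if drug in p.drug_mentions}
    for p in drug_posts.values():
        q = quarter_label(p.timestamp)
        if q in n_posts:
            n_posts[q] += 1

    # one contribution per (post, PT) even if events repeat
    post_pts: dict[str, set[str]] = {}
    for e in events:
        if e.post_id in drug_posts:
            post_pts.setdefault(e.post_id, set()).add(e.pt_code)
    for pid, pts in post_pts.items():
        q = quarter_label(drug_posts[pid].timestamp)
        if q not in n_posts:
            continue
        any_ae[q] += 1
        for pt in pts:
            pt_counts[q][pt] = pt_counts[q].get(pt, 0) + 1

    return QuarterlySummary(drug, quarters, n_posts, pt_counts, any_ae)


@dataclass
class FrequencySeries:
    """Quarterly and overall AE frequency among posts mentioning one drug."""

    drug: str
    pt_code: str                      # a PT code or ANY_AE
    quarters: list[str]
    N_q: np.ndarray                   # drug posts per quarter
    n_q: np.ndarray                   # drug+PT posts per quarter
    decimals: int = field(default=3)  # presentation precision

    def __post_init__(self) -> None:
        self.N_q = np.asarray(self.N_q, dtype=int)
        self.n_q = np.asarray(self.n_q, dtype=int)
        if np.any(self.n_q > self.N_q) or np.any(self.n_q < 0):
            raise ValueError("require 0 <= n_q <= N_q in every quarter")

    @property
    def N(self) -> int:
        return int(self.N_q.sum())

    @property
    def n(self) -> int:
        return int(self.n_q.sum())

    @property
    def f(self) -> float:
        """Overall frequency, percent, full precision."""
        if self.N == 0:
            return math.nan
        return 100.0 * self.n / self.N

    @property
    def f_q(self) -> np.ndarray:
        """Quarterly frequencies, percent; NaN where N_q = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.N_q > 0, 100.0 * self.n_q / np.maximum(self.N_q, 1), np.nan)

    @property
    def f_presented(self) -> float:
        return round_half_away(self.f, self.decimals)

    def sufficient(self, min_cumulative: int = DEFAULT_MIN_CUMULATIVE_COUNT) -> bool:
        """Whether the series clears the cumulative-count gate for trend reading."""
        return self.n >= min_cumulative

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": self.drug,
                "pt_code": self.pt_code,
                "quarter": self.quarters,
                "N": self.N_q,
                "n": self.n_q,
                "f": self.f_q,
            }
        )

    def cumulative(self) -> "FrequencySeries":
        """Cumulative-by-quarter variant (for symmetry with cumulative EBGM)."""
        return FrequencySeries(
            self.drug, self.pt_code, list(self.quarters),
            np.cumsum(self.N_q), np.cumsum(self.n_q), self.decimals,
        )

    @classmethod
    def from_overall(
        cls, drug: str, pt_code: str, n: int, N: int, decimals: int | None = None
    ) -> "FrequencySeries":
        """Single-bucket series from printed overall totals."""
        if decimals is None:
            decimals = 1 if pt_code == ANY_AE else 3
        return cls(drug, pt_code, ["overall"], np.array([N]), np.array([n]), decimals)


def frequency_series(summary: QuarterlySummary, pt_or_any: str = ANY_AE) -> FrequencySeries:
    """Build a FrequencySeries for one PT (or ANY_AE) from a quarterly summary."""
    N_q = np.array([summary.n_posts[q] for q in summary.quarters])
    if pt_or_any == ANY_AE:
        n_q = np.array([summary.any_ae_counts[q] for q in summary.quarters])
        decimals = 1
    else:
        n_q = np.array([summary.pt_counts[q].get(pt_or_any, 0) for q in summary.quarters])
        decimals = 3
    return FrequencySeries(summary.drug, pt_or_any, list(summary.quarters), N_q, n_q, decimals)


def relative_change(f_start: float, f_end: float) -> float:
    """Percent change 100*(f_end - f_start)/f_start; f_start must be positive.

    Full precision is returned; round half away from zero to integer at
    presentation (``round_half_away(value, 0)``).
    """
    if not f_start > 0:
        raise ValueError("relative change is undefined for a non-positive start value")
    return 100.0 * (f_end - f_start) / f_start


def series_to_csv(series: Sequence[FrequencySeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)
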