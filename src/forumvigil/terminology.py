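"""Dictionary-based adverse-event term mapping against a 4-level hierarchy.

Verbatim strings in post text are matched case-insensitively on word
boundaries against a synonym lexicon and aligned to preferred-term (PT)
codes; PTs roll up through high-level term (HLT) and high-level group term
(HLGT) to system organ class (SOC).  The hierarchy mirrors the structure of
regulatory medical terminologies; the shipped fixture content is synthetic.

Matching is longest-match-first: shorter candidate matches overlapping an
accepted longer match are suppressed, and a PT is counted at most once per
post regardless of how many times it is mentioned.  No negation, hypothesis,
or third-party-speaker filtering is applied.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .ingest import CleanPost, Post

LEVELS = ("PT", "HLT", "HLGT", "SOC")


class TerminologyError(ValueError):
    """The terminology file violates a structural invariant."""


def _term_regex(surface: str) -> re.Pattern[str]:
    # word boundary = alphanumeric/non-alphanumeric transition; hyphens
    # inside a term are ordinary characters.
    body = re.escape(surface.strip().lower())
    body = re.sub(r"\\[ ]", r"\\s+", body)
    return re.compile(rf"(?<![0-9A-Za-z]){body}(?![0-9A-Za-z])", re.IGNORECASE)


@dataclass(frozen=True)
class MatchedEvent:
    """One deduplicated PT hit in a post, with the matched surface span."""

    post_id: str
    pt_code: str
    matched_verbatim: str
    start: int
    end: int


@dataclass
class Terminology:
    """Synonym lexicon plus PT -> HLT -> HLGT -> SOC hierarchy."""

    synonyms: dict[str, str]            # surface (lowercased) -> pt_code
    pt_names: dict[str, str]            # pt_code -> display name
    pt_to_hlt: dict[str, str]
    hlt_to_hlgt: dict[str, str]
    hlgt_to_soc: dict[str, str]
    version: str = "synthetic-fixture"
    _patterns: list[tuple[re.Pattern[str], str, str]] = field(
        default_factory=list, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()
        # Surfaces sorted longest-first then lexicographic: match order is
        # independent of file order.
        self._patterns = [
            (_term_regex(s), s, pt)
            for s, pt in sorted(self.synonyms.items(), key=lambda kv: (-len(kv[0]), kv[0]))
        ]

    def validate(self) -> None:
        for surface, pt in self.synonyms.items():
            if pt not in self.pt_to_hlt:
                raise TerminologyError(
                    f"synonym {surface!r} maps to PT {pt} absent from the hierarchy"
                )
        for pt, hlt in self.pt_to_hlt.items():
            if hlt not in self.hlt_to_hlgt:
                raise TerminologyError(f"PT {pt}: HLT {hlt} has no HLGT parent")
        for hlt, hlgt in self.hlt_to_hlgt.items():
            if hlgt not in self.hlgt_to_soc:
                raise TerminologyError(f"HLT {hlt}: HLGT {hlgt} has no SOC parent")
        levels = [set(self.pt_to_hlt), set(self.hlt_to_hlgt), set(self.hlgt_to_soc),
                  set(self.hlgt_to_soc.values())]
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                if a & b:
                    raise TerminologyError(f"codes reused across levels: {sorted(a & b)}")

    @property
    def pt_codes(self) -> set[str]:
        return set(self.pt_to_hlt)

    def ancestors(self, pt_code: str) -> dict[str, str]:
        """Full path {level: code} for a PT."""
        if pt_code not in self.pt_to_hlt:
            raise TerminologyError(f"unknown PT code: {pt_code}")
        hlt = self.pt_to_hlt[pt_code]
        hlgt = self.hlt_to_hlgt[hlt]
        soc = self.hlgt_to_soc[hlgt]
        return {"PT": pt_code, "HLT": hlt, "HLGT": hlgt, "SOC": soc}

    # ------------------------------------------------------------------
    @classmethod
    def from_rows(cls, rows: Iterable[Mapping[str, str]], version: str = "synthetic-fixture") -> "Terminology":
        """Build from rows with columns synonym,pt_code,pt_name,hlt_code,hlgt_code,soc_code."""
        synonyms: dict[str, str] = {}
        pt_names: dict[str, str] = {}
        pt_to_hlt: dict[str, str] = {}
        hlt_to_hlgt: dict[str, str] = {}
        hlgt_to_soc: dict[str, str] = {}
        for row in rows:
            surface = row["synonym"].strip().lower()
            pt = row["pt_code"].strip()
            if surface in synonyms and synonyms[surface] != pt:
                raise TerminologyError(
                    f"synonym {surface!r} mapped to two PTs: {synonyms[surface]}, {pt}"
                )
            synonyms[surface] = pt
            pt_names.setdefault(pt, row.get("pt_name", pt))
            for child, parent, table in (
                (pt, row["hlt_code"].strip(), pt_to_hlt),
                (row["hlt_code"].strip(), row["hlgt_code"].strip(), hlt_to_hlgt),
                (row["hlgt_code"].strip(), row["soc_code"].strip(), hlgt_to_soc),
            ):
                if child in table and table[child] != parent:
                    raise TerminologyError(
                        f"code {child} has two parents: {table[child]}, {parent}"
                    )
                table[child] = parent
        return cls(synonyms, pt_names, pt_to_hlt, hlt_to_hlgt, hlgt_to_soc, version)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["synonym", "pt_code", "pt_name", "hlt_code", "hlgt_code", "soc_code"])
            for surface, pt in sorted(self.synonyms.items()):
                path_codes = self.ancestors(pt)
                w.writerow([surface, pt, self.pt_names[pt],
                            path_codes["HLT"], path_codes["HLGT"], path_codes["SOC"]])


def load_terminology(path: str | Path) -> Terminology:
    """Load and validate a terminology CSV; fails atomically on any defect."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"synonym", "pt_code", "pt_name", "hlt_code", "hlgt_code", "soc_code"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TerminologyError(f"terminology CSV must have columns {sorted(required)}")
        return Terminology.from_rows(list(reader))


def match_events(post: Post | CleanPost, term: Terminology) -> list[MatchedEvent]:
    """Scan a post's (masked) text for terminology hits.

    Longest match wins at each position; overlapping shorter matches are
    suppressed; each PT is reported at most once per post (first accepted
    occurrence).  Returned events are ordered by span start.
    """
    text = post.masked_text if isinstance(post, CleanPost) else post.text
    candidates: list[tuple[int, int, str, str]] = []  # (start, -len, surface, pt)
    for pattern, surface, pt in term._patterns:
        for m in pattern.finditer(text):
            candidates.append((m.start(), -(m.end() - m.start()), surface, pt))
    candidates.sort()
    accepted: list[MatchedEvent] = []
    occupied: list[tuple[int, int]] = []
    seen_pts: set[str] = set()
    for start, neglen, surface, pt in candidates:
        end = start - neglen
        if any(start < e and s < end for s, e in occupied):
            continue
        occupied.append((start, end))
        if pt in seen_pts:
            continue
        seen_pts.add(pt)
        accepted.append(MatchedEvent(post.post_id, pt, text[start:end], start, end))
    return accepted


def roll_up(pt_code: str, level: str, term: Terminology) -> str:
    """Return the unique ancestor of a PT at HLT, HLGT, or SOC level."""
    if level not in ("HLT", "HLGT", "SOC"):
        raise ValueError(f"level must be one of HLT/HLGT/SOC, got {level!r}")
    return term.ancestors(pt_code)[level]


def events_to_csv(events: Iterable[MatchedEvent], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["post_id", "pt_code", "verbatim", "start", "end"])
        for e in events:
            w.writerow([e.post_id, e.pt_code, e.matched_verbatim, e.start, e.end])
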