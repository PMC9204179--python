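"""Longitudinal author dossiers, complexity scoring, and insight coverage.

Posts sharing an author identifier are linked into a time-ordered dossier.
Each dossier is scored with a configurable registry of indicators (default:
28 binary presence/threshold indicators with unit weights); the score
S = sum_k u_k * I_k ranks dossiers for manual review.  Coverage of seven
medical-insight categories (and, where an adverse event is mentioned, six
AE sub-elements) is summarized over annotated groups, cumulatively across an
author's posts versus within single posts.

The exact indicator definitions of published complexity scores are not
public; the default registry documented here preserves the scoring
architecture with openly stated lexicons and thresholds.  The bundled
lexicon-based auto-annotator exists for synthetic-data testing only and is
not a clinical annotation tool.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from ._text import phrase_regex, round_half_away, tokenize
from .ingest import CleanPost
from .terminology import MatchedEvent

INSIGHT_CATEGORIES = (
    "medical_history",
    "disease_burden",
    "non_medical_treatments",
    "laboratory_results",
    "treatment_history",
    "concomitant_medications",
    "ae_mention",
)

AE_SUBELEMENTS = (
    "time_to_onset",
    "outcome",
    "treatment_of_ae",
    "causality_statement",
    "dose",
    "rechallenge_dechallenge",
)

# Severity vocabulary folds into disease_burden; co-suspect drug mentions fold
# into concomitant_medications (keeps the default registry at exactly 28).
INSIGHT_LEXICONS: dict[str, list[str]] = {
    "medical_history": ["diagnosed", "history of", "my condition", "years ago i had"],
    "disease_burden": ["pain", "struggling", "severe", "worse", "flare", "unbearable"],
    "non_medical_treatments": ["yoga", "vitamin", "supplement", "acupuncture", "special diet"],
    "laboratory_results": ["lab results", "blood test", "calcium level", "results came back"],
    "treatment_history": ["used to take", "previously on", "switched from", "stopped taking"],
    "concomitant_medications": ["also take", "also taking", "along with", "together with"],
    "ae_mention": ["side effect", "reaction", "after taking", "it caused"],
    "time_to_onset": ["days after", "weeks after", "hours after", "soon after", "months after"],
    "outcome": ["recovered", "resolved", "went away", "still ongoing", "hospitalized"],
    "treatment_of_ae": ["treated with", "was prescribed", "to manage it"],
    "causality_statement": ["because of", "due to", "caused by", "from the drug"],
    "dose": ["dose", "dosage", "half the"],
    "rechallenge_dechallenge": ["stopped and restarted", "came back when", "after stopping", "restarted"],
    "first_person": ["i", "my", "me", "mine"],
    "hcp_visit": ["doctor", "oncologist", "appointment", "clinic", "specialist", "nurse"],
    "treatment_switch": ["switched to", "changed to", "moved to"],
    "family_caregiver_voice": ["my mother", "my husband", "my wife", "my son", "my daughter", "caregiver"],
}

_TEMPORAL_RE = re.compile(
    r"(?<![0-9A-Za-z])(yesterday|today|ago|since|last (?:week|month|year)|"
    r"\d+ (?:day|week|month|year)s?)(?![0-9A-Za-z])",
    re.IGNORECASE,
)
_DOSAGE_RE = re.compile(r"\d+\s?(mg|mcg|ml|units?)(?![0-9A-Za-z])", re.IGNORECASE)
_LABVALUE_RE = re.compile(r"\d+(\.\d+)?\s?(mg/dl|mmol/l|g/l|iu/l)(?![0-9A-Za-z])", re.IGNORECASE)
_NEGATION = {"no", "not", "never", "without", "didnt", "dont", "cant"}


class ValidationError(ValueError):
    """An annotation or dossier violates a structural invariant."""


@dataclass
class AuthorDossier:
    """Time-ordered posts of one author, with optional score state."""

    author_id: str
    posts: list[CleanPost]
    pt_codes: set[str] = field(default_factory=set)
    indicator_vector: np.ndarray | None = None
    complexity: float | None = None

    @property
    def text(self) -> str:
        return "\n".join(p.masked_text for p in self.posts).lower()

    @property
    def first_post_at(self):
        return self.posts[0].timestamp

    @property
    def span_days(self) -> float:
        return (self.posts[-1].timestamp - self.posts[0].timestamp).total_seconds() / 86400.0

    @property
    def n_threads(self) -> int:
        return len({p.thread_id for p in self.posts})


def build_dossiers(
    posts: Iterable[CleanPost],
    events: Iterable[MatchedEvent] | None = None,
) -> list[AuthorDossier]:
    """Partition posts into one dossier per author (sorted by time, then id)."""
    posts = list(posts)
    missing = [p.post_id for p in posts if not p.author_id]
    if missing:
        raise ValidationError(f"posts lack an author_id: {missing}")
    pt_by_post: dict[str, set[str]] = {}
    for e in events or []:
        pt_by_post.setdefault(e.post_id, set()).add(e.pt_code)

    groups: dict[str, list[CleanPost]] = {}
    for p in posts:
        groups.setdefault(p.author_id, []).append(p)
    dossiers = []
    for author in sorted(groups):
        ordered = sorted(groups[author], key=lambda p: (p.timestamp, p.post_id))
        pts: set[str] = set()
        for p in ordered:
            pts |= pt_by_post.get(p.post_id, set())
        dossiers.append(AuthorDossier(author, ordered, pts))
    return dossiers


# ---------------------------------------------------------------------------
# Indicator registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Indicator:
    name: str
    fn: Callable[[AuthorDossier], float]
    weight: float = 1.0


def _lexicon_indicator(name: str) -> Callable[[AuthorDossier], float]:
    if name == "first_person":
        words = set(INSIGHT_LEXICONS[name])

        def hit_tokens(d: AuthorDossier) -> float:
            return float(bool(words & set(tokenize(d.text))))

        return hit_tokens
    patterns = [phrase_regex(s) for s in INSIGHT_LEXICONS[name]]

    def hit(d: AuthorDossier) -> float:
        text = d.text
        return float(any(p.search(text) for p in patterns))

    return hit


def default_registry() -> list[Indicator]:
    """The default 28-indicator profile (binary presence/threshold, unit weights)."""
    reg: list[Indicator] = [
        Indicator("drug_mention", lambda d: float(any(p.drug_mentions for p in d.posts))),
        Indicator("distinct_pts_ge_2", lambda d: float(len(d.pt_codes) >= 2)),
        Indicator("distinct_pts_ge_5", lambda d: float(len(d.pt_codes) >= 5)),
        Indicator("temporal_expression", lambda d: float(bool(_TEMPORAL_RE.search(d.text)))),
        Indicator("dosage_pattern", lambda d: float(bool(_DOSAGE_RE.search(d.text)))),
        Indicator("lab_value_pattern", lambda d: float(bool(_LABVALUE_RE.search(d.text)))),
        Indicator("negation_marker", lambda d: float(bool(_NEGATION & set(tokenize(d.text))))),
        Indicator("question_form", lambda d: float("?" in d.text)),
        Indicator("posts_ge_10", lambda d: float(len(d.posts) >= 10)),
        Indicator("span_ge_90_days", lambda d: float(d.span_days >= 90.0)),
        Indicator("threads_ge_3", lambda d: float(d.n_threads >= 3)),
    ]
    for cat in INSIGHT_CATEGORIES:
        reg.append(Indicator(f"insight_{cat}", _lexicon_indicator(cat)))
    for sub in AE_SUBELEMENTS:
        reg.append(Indicator(f"ae_{sub}", _lexicon_indicator(sub)))
    for extra in ("first_person", "hcp_visit", "treatment_switch", "family_caregiver_voice"):
        reg.append(Indicator(extra, _lexicon_indicator(extra)))
    return reg


DEFAULT_REGISTRY_SIZE = 28


def complexity_score(
    dossier: AuthorDossier,
    registry: Sequence[Indicator] | None = None,
    expected_size: int | None = None,
) -> tuple[float, np.ndarray]:
    """S = sum_k u_k * I_k(dossier); each I_k is a pure function into [0,1].

    The dossier's ``indicator_vector`` and ``complexity`` are filled in.
    For the default profile the registry size must be 28.
    """
    if registry is None:
        registry = default_registry()
        expected_size = DEFAULT_REGISTRY_SIZE
    if expected_size is not None and len(registry) != expected_size:
        raise ValidationError(
            f"registry has {len(registry)} indicators, expected {expected_size}"
        )
    values = np.array([ind.fn(dossier) for ind in registry], dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValidationError("indicator values must lie in [0,1]")
    weights = np.array([ind.weight for ind in registry], dtype=float)
    score = float(weights @ values)
    dossier.indicator_vector = values
    dossier.complexity = score
    return score, values


def rank_dossiers(dossiers: Sequence[AuthorDossier], k: int) -> list[AuthorDossier]:
    """Top-k dossiers by complexity (ties: earlier first post, then author id)."""
    if k > len(dossiers):
        raise ValueError(f"k={k} exceeds the number of dossiers ({len(dossiers)})")
    for d in dossiers:
        if d.complexity is None:
            complexity_score(d)
    ordered = sorted(dossiers, key=lambda d: (-d.complexity, d.first_post_at, d.author_id))
    return ordered[:k]


def posts_per_author(dossiers: Sequence[AuthorDossier]) -> dict[str, float]:
    """Posts-per-author summary; the presented mean is truncated to whole posts."""
    sizes = np.array([len(d.posts) for d in dossiers])
    return {
        "n_authors": int(len(sizes)),
        "n_posts": int(sizes.sum()),
        "mean": float(sizes.mean()),
        "mean_presented": int(sizes.mean()),  # truncation, matching field convention
        "median": float(np.median(sizes)),
        "min": int(sizes.min()),
        "max": int(sizes.max()),
    }


# ---------------------------------------------------------------------------
# Insight annotations and coverage
# ---------------------------------------------------------------------------

class InsightAnnotation(BaseModel):
    """Expert annotation of one group of linked posts (or one single post)."""

    model_config = ConfigDict(frozen=True)

    group_id: str
    medical_history: bool = False
    disease_burden: bool = False
    non_medical_treatments: bool = False
    laboratory_results: bool = False
    treatment_history: bool = False
    concomitant_medications: bool = False
    ae_mention: bool = False
    time_to_onset: bool = False
    outcome: bool = False
    treatment_of_ae: bool = False
    causality_statement: bool = False
    dose: bool = False
    rechallenge_dechallenge: bool = False

    @model_validator(mode="after")
    def _subelements_need_ae(self) -> "InsightAnnotation":
        if not self.ae_mention:
            offending = [s for s in AE_SUBELEMENTS if getattr(self, s)]
            if offending:
                raise ValueError(
                    f"AE sub-elements {offending} set without ae_mention on {self.group_id!r}"
                )
        return self

    def all_seven(self) -> bool:
        return all(getattr(self, c) for c in INSIGHT_CATEGORIES)


@dataclass(frozen=True)
class CoverageReport:
    n_groups: int
    category_counts: dict[str, int]
    category_pct: dict[str, float]          # rounded half away from zero
    subelement_counts: dict[str, int]
    subelement_pct: dict[str, float]        # denominator = n_groups, as printed
    n_all_seven: int
    pct_all_seven: float
    n_single_posts: int | None = None
    n_single_posts_all_seven: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"element": c, "kind": "category", "count": self.category_counts[c],
             "pct": self.category_pct[c]}
            for c in INSIGHT_CATEGORIES
        ] + [
            {"element": s, "kind": "ae_subelement", "count": self.subelement_counts[s],
             "pct": self.subelement_pct[s]}
            for s in AE_SUBELEMENTS
        ]
        return pd.DataFrame(rows)


def insight_coverage(
    annotations: Sequence[InsightAnnotation],
    per_post_annotations: Sequence[InsightAnnotation] | None = None,
) -> CoverageReport:
    """Category and sub-element coverage over annotated groups.

    Sub-element percentages use the full group count as denominator (the
    printed convention), even though sub-elements can only be true where an
    AE is mentioned.  ``per_post_annotations`` additionally yields the count
    of single posts carrying all seven categories at once.
    """
    n = len(annotations)
    if n == 0:
        raise ValidationError("no annotations supplied")
    cat_counts = {c: sum(getattr(a, c) for a in annotations) for c in INSIGHT_CATEGORIES}
    sub_counts = {s: sum(getattr(a, s) for a in annotations) for s in AE_SUBELEMENTS}
    n_all = sum(a.all_seven() for a in annotations)
    pct = lambda c: round_half_away(100.0 * c / n, 0)

    n_single = n_single_all = None
    if per_post_annotations is not None:
        n_single = len(per_post_annotations)
        n_single_all = sum(a.all_seven() for a in per_post_annotations)

    return CoverageReport(
        n_groups=n,
        category_counts=cat_counts,
        category_pct={c: pct(v) for c, v in cat_counts.items()},
        subelement_counts=sub_counts,
        subelement_pct={s: pct(v) for s, v in sub_counts.items()},
        n_all_seven=n_all,
        pct_all_seven=pct(n_all),
        n_single_posts=n_single,
        n_single_posts_all_seven=n_single_all,
    )


def auto_annotate(dossier: AuthorDossier, group_id: str | None = None) -> InsightAnnotation:
    """Lexicon-based annotation of a dossier — for synthetic tests only, non-clinical."""
    text = dossier.text
    flags = {
        name: bool(any(phrase_regex(s).search(text) for s in INSIGHT_LEXICONS[name]))
        for name in INSIGHT_CATEGORIES + AE_SUBELEMENTS
    }
    if not flags["ae_mention"]:
        for s in AE_SUBELEMENTS:
            flags[s] = False
    return InsightAnnotation(group_id=group_id or dossier.author_id, **flags)


# ---------------------------------------------------------------------------
# Annotation CSV I/O (group_id plus 13 boolean columns)
# ---------------------------------------------------------------------------

_BOOL_COLS = list(INSIGHT_CATEGORIES) + list(AE_SUBELEMENTS)


def read_annotations_csv(path) -> list[InsightAnnotation]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            fields = {"group_id": row["group_id"]}
            for col in _BOOL_COLS:
                fields[col] = row.get(col, "").strip().lower() in ("1", "true", "yes")
            out.append(InsightAnnotation(**fields))
    return out


def write_annotations_csv(annotations: Iterable[InsightAnnotation], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["group_id"] + _BOOL_COLS)
        for a in annotations:
            w.writerow([a.group_id] + [int(getattr(a, c)) for c in _BOOL_COLS])
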