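"""Synthetic inputs with known ground truth for every pipeline stage.

Generates forum corpora with planted artifacts (exact duplicates, spam posts
carrying lexicon keywords, inserted person names, drug keywords, and
adverse-event verbatims with quarter-varying injection rates), labeled
training posts for the AE text classifier, and simulated spontaneous-report
tables drawn from the gamma-Poisson mixture with known relative-risk
signals.

Text synthesis is template-based: slot-filled drug names, AE synonyms, and
filler vocabulary.  Dictionary matching — not language fidelity — is what the
downstream stages exercise, so the filler, spam, name, drug, and synonym
vocabularies are kept pairwise disjoint, making planted artifacts exactly
recoverable.  All randomness flows from a single config seed; each generator
stage draws from its own fixed-offset sub-stream so adding one stage never
perturbs another.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._text import quarter_bounds, quarter_range, tokenize
from .disproportionality import MixturePrior
from .ingest import ConfigurationError, Post
from .terminology import Terminology

# ---------------------------------------------------------------------------
# Default fixtures (synthetic stand-ins for licensed terminology content and
# curated word lists; structure matches the real artifacts, content does not)
# ---------------------------------------------------------------------------

_TERMINOLOGY_ROWS: list[tuple[str, str, str, str, str, str]] = [
    # synonym, pt_code, pt_name, hlt, hlgt, soc
    ("spinal fracture", "PT0001", "Spinal fracture", "HLT01", "HLGT01", "SOC01"),
    ("spine fracture", "PT0001", "Spinal fracture", "HLT01", "HLGT01", "SOC01"),
    ("fractured spine", "PT0001", "Spinal fracture", "HLT01", "HLGT01", "SOC01"),
    ("thoracic vertebral fracture", "PT0002", "Thoracic vertebral fracture", "HLT01", "HLGT01", "SOC01"),
    ("thoracic spine fracture", "PT0002", "Thoracic vertebral fracture", "HLT01", "HLGT01", "SOC01"),
    ("lumbar vertebral fracture", "PT0003", "Lumbar vertebral fracture", "HLT01", "HLGT01", "SOC01"),
    ("lumbar spine fracture", "PT0003", "Lumbar vertebral fracture", "HLT01", "HLGT01", "SOC01"),
    ("cervical vertebral fracture", "PT0004", "Cervical vertebral fracture", "HLT01", "HLGT01", "SOC01"),
    ("osteoporosis", "PT0005", "Osteoporosis", "HLT02", "HLGT01", "SOC01"),
    ("brittle bones", "PT0005", "Osteoporosis", "HLT02", "HLGT01", "SOC01"),
    ("bone pain", "PT0006", "Bone pain", "HLT02", "HLGT01", "SOC01"),
    ("stevens-johnson syndrome", "PT0007", "Stevens-Johnson syndrome", "HLT03", "HLGT02", "SOC02"),
    ("toxic epidermal necrolysis", "PT0008", "Toxic epidermal necrolysis", "HLT03", "HLGT02", "SOC02"),
    ("exfoliative dermatitis", "PT0009", "Dermatitis exfoliative", "HLT03", "HLGT02", "SOC02"),
    ("skin peeling", "PT0009", "Dermatitis exfoliative", "HLT03", "HLGT02", "SOC02"),
    ("pemphigoid", "PT0010", "Pemphigoid", "HLT03", "HLGT02", "SOC02"),
    ("blistering rash", "PT0010", "Pemphigoid", "HLT03", "HLGT02", "SOC02"),
    ("skin rash", "PT0011", "Rash", "HLT04", "HLGT02", "SOC02"),
    ("itchy rash", "PT0011", "Rash", "HLT04", "HLGT02", "SOC02"),
    ("fatigue", "PT0012", "Fatigue", "HLT05", "HLGT03", "SOC03"),
    ("exhausted", "PT0012", "Fatigue", "HLT05", "HLGT03", "SOC03"),
    ("nausea", "PT0013", "Nausea", "HLT05", "HLGT03", "SOC03"),
    ("queasy", "PT0013", "Nausea", "HLT05", "HLGT03", "SOC03"),
    ("headache", "PT0014", "Headache", "HLT06", "HLGT03", "SOC03"),
    ("joint pain", "PT0015", "Arthralgia", "HLT06", "HLGT03", "SOC03"),
    ("arthralgia", "PT0015", "Arthralgia", "HLT06", "HLGT03", "SOC03"),
    ("malignant melanoma", "PT0016", "Malignant melanoma", "HLT07", "HLGT04", "SOC04"),
    ("melanoma", "PT0016", "Malignant melanoma", "HLT07", "HLGT04", "SOC04"),
]

DEFAULT_SPAM_LEXICON = [
    "online store", "buy now", "discount code", "press release",
    "free shipping", "limited offer",
]

DEFAULT_NAME_DICTIONARY = [
    "mary", "john", "susan", "david", "karen", "michael", "linda", "james",
    "barbara", "robert", "patricia", "william", "jennifer", "richard",
    "elizabeth", "thomas",
]

DEFAULT_DRUG_LEXICONS: dict[str, dict[str, list[str]]] = {
    "denosumab": {
        "generic": ["denosumab"],
        "brand": ["prolia", "xgeva"],
        "class": ["antiresorptive"],
    },
    "pembrolizumab": {
        "generic": ["pembrolizumab"],
        "brand": ["keytruda"],
        "class": ["checkpoint inhibitor"],
    },
}

_FILLER = [
    "morning", "everyone", "sharing", "update", "journey", "community",
    "weekend", "garden", "coffee", "reading", "posting", "thoughts",
    "wishes", "sunshine", "grateful", "hello", "friends", "weather",
    "support", "chatting",
]


def default_terminology() -> Terminology:
    rows = [
        dict(zip(("synonym", "pt_code", "pt_name", "hlt_code", "hlgt_code", "soc_code"), r))
        for r in _TERMINOLOGY_ROWS
    ]
    return Terminology.from_rows(rows)


# ---------------------------------------------------------------------------
# Corpus configuration and ground truth
# ---------------------------------------------------------------------------

class InjectionSchedule(BaseModel):
    """Per-quarter mention probability of a PT among posts of one drug."""

    model_config = ConfigDict(frozen=True)

    drug: str
    pt_code: str
    kind: Literal["constant", "ramp", "step"] = "constant"
    p_start: float = Field(ge=0.0, le=1.0)
    p_end: float | None = Field(default=None, ge=0.0, le=1.0)
    step_quarter: str | None = None

    def probability(self, quarter: str, quarters: Sequence[str]) -> float:
        idx = list(quarters).index(quarter)
        if self.kind == "constant":
            return self.p_start
        if self.kind == "ramp":
            if len(quarters) == 1:
                return self.p_start
            frac = idx / (len(quarters) - 1)
            return self.p_start + frac * (self.p_end - self.p_start)
        # step
        step_idx = list(quarters).index(self.step_quarter)
        return self.p_start if idx < step_idx else self.p_end

    @model_validator(mode="after")
    def _check(self) -> "InjectionSchedule":
        if self.kind in ("ramp", "step") and self.p_end is None:
            raise ValueError(f"{self.kind} schedule requires p_end")
        if self.kind == "step" and self.step_quarter is None:
            raise ValueError("step schedule requires step_quarter")
        return self


class CorpusConfig(BaseModel):
    """Study conditions for one synthetic forum corpus."""

    model_config = ConfigDict(frozen=True)

    fora: list[str] = Field(default=["inspire", "breastcancer", "healthunlocked", "melanoma"])
    n_authors: int = Field(default=300, gt=0)
    n_posts: int = Field(default=5000, gt=0)
    period: tuple[str, str] = ("2010Q3", "2021Q1")
    drug_lexicons: dict[str, dict[str, list[str]]] = Field(
        default_factory=lambda: {k: {kk: list(vv) for kk, vv in v.items()}
                                 for k, v in DEFAULT_DRUG_LEXICONS.items()}
    )
    ae_injection: list[InjectionSchedule] = Field(default_factory=list)
    dup_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    spam_rate: float = Field(default=0.03, ge=0.0, le=1.0)
    pii_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    relevance_rate: float = Field(default=0.85, ge=0.0, le=1.0)
    author_skew: float = Field(default=1.0, ge=0.0)
    seed: int = 0

    @property
    def quarters(self) -> list[str]:
        return quarter_range(*self.period)

    @model_validator(mode="after")
    def _check(self) -> "CorpusConfig":
        quarter_range(*self.period)  # raises on an empty period
        if not self.fora:
            raise ValueError("need at least one forum")
        return self


@dataclass
class PostTruth:
    is_duplicate_of: str | None = None
    is_spam: bool = False
    is_relevant: bool = False
    drugs: set[str] = field(default_factory=set)
    inserted_names: list[str] = field(default_factory=list)
    true_pt_mentions: set[str] = field(default_factory=set)


@dataclass
class GroundTruth:
    """Planted-artifact index for a generated corpus."""

    posts: dict[str, PostTruth]
    planted_probability: dict[tuple[str, str, str], float]  # (drug, pt, quarter) -> p

    def duplicate_ids(self) -> set[str]:
        return {pid for pid, t in self.posts.items() if t.is_duplicate_of is not None}

    def spam_ids(self) -> set[str]:
        return {pid for pid, t in self.posts.items() if t.is_spam}

    def relevant_ids(self) -> set[str]:
        return {pid for pid, t in self.posts.items() if t.is_relevant}

    def pt_mentions(self, post_id: str) -> set[str]:
        return self.posts[post_id].true_pt_mentions


def _check_disjoint_vocab(config: CorpusConfig, term: Terminology,
                          spam: Sequence[str], names: Sequence[str]) -> None:
    pools: dict[str, set[str]] = {
        "filler": set(_FILLER),
        "spam": {w for p in spam for w in tokenize(p)},
        "names": {n.lower() for n in names},
        "drugs": {w for lex in config.drug_lexicons.values()
                  for kws in lex.values() for k in kws for w in tokenize(k)},
        "synonyms": {w for s in term.synonyms for w in tokenize(s)},
    }
    keys = list(pools)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            clash = pools[a] & pools[b]
            if clash:
                raise ConfigurationError(
                    f"vocabulary overlap between {a} and {b}: {sorted(clash)} — "
                    "ground-truth recovery would be ambiguous"
                )


# sub-stream offsets (fixed; adding a stage never perturbs another)
_STREAMS = {"structure": 0, "dup": 1, "spam": 2, "relevance": 3,
            "injection": 4, "pii": 5, "text": 6}


def generate_corpus(
    config: CorpusConfig,
    terminology: Terminology | None = None,
    spam_lexicon: Sequence[str] = DEFAULT_SPAM_LEXICON,
    name_dictionary: Sequence[str] = DEFAULT_NAME_DICTIONARY,
) -> tuple[list[Post], GroundTruth]:
    """Emit ``config.n_posts`` posts (duplicates included) plus ground truth.

    Duplicate posts are byte-identical copies of an earlier original with the
    same author and timestamp (and a larger post_id, so the dedup tie-break
    keeps the original).  Spam posts carry >=1 spam-lexicon phrase and no
    drug keyword; relevant posts carry >=1 drug keyword; planted AE verbatims
    are surface synonyms of the scheduled PT.
    """
    term = terminology if terminology is not None else default_terminology()
    for sched in config.ae_injection:
        if sched.pt_code not in term.pt_codes:
            raise ConfigurationError(
                f"ae_injection references unknown PT code {sched.pt_code!r}"
            )
        if sched.drug not in config.drug_lexicons:
            raise ConfigurationError(
                f"ae_injection references unknown drug {sched.drug!r}"
            )
        if sched.kind == "step" and sched.step_quarter not in config.quarters:
            raise ConfigurationError(
                f"step quarter {sched.step_quarter!r} outside the period"
            )
    _check_disjoint_vocab(config, term, spam_lexicon, name_dictionary)

    rngs = {k: np.random.default_rng([config.seed, off]) for k, off in _STREAMS.items()}
    quarters = config.quarters

    # stable synonym list per PT
    pt_synonyms: dict[str, list[str]] = {}
    for surface, pt in sorted(term.synonyms.items()):
        pt_synonyms.setdefault(pt, []).append(surface)

    weights = rngs["structure"].lognormal(0.0, config.author_skew, config.n_authors)
    weights /= weights.sum()
    authors = [f"a{i:05d}" for i in range(config.n_authors)]
    n_threads = max(3, config.n_posts // 8)

    drugs = sorted(config.drug_lexicons)
    drug_keywords = {
        d: sorted(k for kws in lex.values() for k in kws)
        for d, lex in config.drug_lexicons.items()
    }
    schedules_by_drug: dict[str, list[InjectionSchedule]] = {}
    for sched in config.ae_injection:
        schedules_by_drug.setdefault(sched.drug, []).append(sched)

    posts: list[Post] = []
    truth_posts: dict[str, PostTruth] = {}
    originals: list[int] = []  # indices into posts

    for i in range(config.n_posts):
        post_id = f"p{i:07d}"
        if originals and rngs["dup"].random() < config.dup_rate:
            src = posts[originals[int(rngs["dup"].integers(len(originals)))]]
            posts.append(Post(
                forum=src.forum, post_id=post_id, thread_id=src.thread_id,
                author_id=src.author_id, timestamp=src.timestamp, text=src.text,
            ))
            src_truth = truth_posts[src.post_id]
            truth_posts[post_id] = PostTruth(
                is_duplicate_of=src.post_id,
                is_spam=src_truth.is_spam,
                is_relevant=src_truth.is_relevant,
                drugs=set(src_truth.drugs),
                inserted_names=list(src_truth.inserted_names),
                true_pt_mentions=set(src_truth.true_pt_mentions),
            )
            continue

        author = authors[int(rngs["structure"].choice(config.n_authors, p=weights))]
        forum = config.fora[int(rngs["structure"].integers(len(config.fora)))]
        quarter = quarters[int(rngs["structure"].integers(len(quarters)))]
        q_start, q_end = quarter_bounds(quarter)
        ts = q_start + timedelta(
            seconds=float(rngs["structure"].random()) * (q_end - q_start).total_seconds()
        )
        ts = ts.replace(microsecond=0)
        thread = f"{forum}-t{int(rngs['structure'].integers(n_threads)):05d}"

        truth = PostTruth()
        filler = rngs["text"].choice(_FILLER, size=6, replace=True)
        sentences = [f"Good {filler[0]} {filler[1]}, just {filler[2]} my {filler[3]}."]

        is_spam = rngs["spam"].random() < config.spam_rate
        if is_spam:
            phrase = spam_lexicon[int(rngs["spam"].integers(len(spam_lexicon)))]
            sentences.append(f"Visit our {phrase} for a {filler[4]} deal.")
            truth.is_spam = True
        elif rngs["relevance"].random() < config.relevance_rate:
            drug = drugs[int(rngs["relevance"].integers(len(drugs)))]
            kws = drug_keywords[drug]
            kw = kws[int(rngs["relevance"].integers(len(kws)))]
            sentences.append(f"I started {kw} and wanted to share my {filler[4]}.")
            truth.is_relevant = True
            truth.drugs.add(drug)
            for sched in schedules_by_drug.get(drug, []):
                p = sched.probability(quarter, quarters)
                if rngs["injection"].random() < p:
                    syns = pt_synonyms[sched.pt_code]
                    syn = syns[int(rngs["injection"].integers(len(syns)))]
                    sentences.append(f"Soon after that {syn} started for me.")
                    truth.true_pt_mentions.add(sched.pt_code)
        else:
            sentences.append(f"Mostly {filler[4]} and {filler[5]} here today.")

        if rngs["pii"].random() < config.pii_rate:
            name = name_dictionary[int(rngs["pii"].integers(len(name_dictionary)))]
            sentences.append(f"Thanks {name.capitalize()} for the kind words.")
            truth.inserted_names.append(name)

        posts.append(Post(
            forum=forum, post_id=post_id, thread_id=thread,
            author_id=author, timestamp=ts, text=" ".join(sentences),
        ))
        truth_posts[post_id] = truth
        originals.append(i)

    planted = {
        (sched.drug, sched.pt_code, q): sched.probability(q, quarters)
        for sched in config.ae_injection
        for q in quarters
    }
    return posts, GroundTruth(truth_posts, planted)


# ---------------------------------------------------------------------------
# Labeled posts for the AE text classifier
# ---------------------------------------------------------------------------

DEFAULT_AE_VOCAB = [
    "rash", "nausea", "fracture", "headache", "dizzy", "swelling",
    "fatigue", "vomiting",
]


@dataclass(frozen=True)
class LabeledPost:
    text: str
    label: int  # 1 = AE, 0 = not AE


def generate_labeled_posts(
    n_pos: int,
    n_neg: int,
    seed: int,
    pos_vocab: Sequence[str] | None = None,
    neg_vocab: Sequence[str] | None = None,
    background: Sequence[str] | None = None,
    pos_rate: float = 0.5,
    neg_rate: float = 0.05,
    doc_len: int = 12,
) -> list[LabeledPost]:
    """Deterministic labeled training posts for the naive Bayes classifier.

    Positive posts draw class-vocabulary words at rate ``pos_rate`` per
    token, negatives at ``neg_rate``; remaining tokens come from background
    filler.  With disjoint class vocabularies and rate 1.0 the classes are
    perfectly separable; with identical vocabularies and equal rates they are
    indistinguishable.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be non-empty (n_pos, n_neg > 0)")
    pos_vocab = list(pos_vocab) if pos_vocab is not None else list(DEFAULT_AE_VOCAB)
    neg_vocab = list(neg_vocab) if neg_vocab is not None else list(pos_vocab)
    background = list(background) if background is not None else list(_FILLER)
    rng = np.random.default_rng(seed)

    def make(vocab: Sequence[str], rate: float) -> str:
        words = [
            str(rng.choice(vocab)) if rng.random() < rate else str(rng.choice(background))
            for _ in range(doc_len)
        ]
        return " ".join(words)

    out = [LabeledPost(make(pos_vocab, pos_rate), 1) for _ in range(n_pos)]
    out += [LabeledPost(make(neg_vocab, neg_rate), 0) for _ in range(n_neg)]
    return out


# ---------------------------------------------------------------------------
# Simulated spontaneous-report tables
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReportSet:
    """Simulated drug x event reports with the generating truth attached."""

    reports: pd.DataFrame            # drug, event_pt, quarter, count, expected
    true_lambda: dict[tuple[str, str], float]
    prior_used: MixturePrior

    def to_csv(self, path) -> None:
        self.reports[["drug", "event_pt", "quarter", "count"]].to_csv(path, index=False)


def _draw_lambda(prior: MixturePrior, size: int, rng: np.random.Generator) -> np.ndarray:
    comp1 = rng.random(size) < prior.pi
    lam = np.where(
        comp1,
        rng.gamma(prior.alpha1, 1.0 / prior.beta1, size),
        rng.gamma(prior.alpha2, 1.0 / prior.beta2, size),
    )
    return lam


def simulate_report_table(
    prior: MixturePrior,
    n_drugs: int,
    n_events: int,
    margins: float | tuple[float, float],
    seed: int,
    quarter: str = "2021Q1",
) -> SimulatedReportSet:
    """Draw each cell's lambda from the two-gamma mixture, then N ~ Poisson(lambda*E).

    ``margins`` sets the expected-count scale: a scalar gives every cell that
    E; a (low, high) pair draws per-cell E log-uniformly.  Deterministic per
    seed; the true lambda of every cell is recorded.
    """
    prior.validate()
    rng = np.random.default_rng(seed)
    n_cells = n_drugs * n_events
    if np.isscalar(margins):
        if margins <= 0:
            raise ValueError("margins must be > 0")
        e = np.full(n_cells, float(margins))
    else:
        lo, hi = margins
        if lo <= 0 or hi < lo:
            raise ValueError("margins range must satisfy 0 < low <= high")
        e = np.exp(rng.uniform(np.log(lo), np.log(hi), n_cells))
    lam = _draw_lambda(prior, n_cells, rng)
    counts = rng.poisson(lam * e)

    drugs = np.repeat([f"D{i:03d}" for i in range(n_drugs)], n_events)
    events = np.tile([f"PT9{j:03d}" for j in range(n_events)], n_drugs)
    reports = pd.DataFrame({
        "drug": drugs, "event_pt": events, "quarter": quarter,
        "count": counts, "expected": e,
    })
    true_lambda = {(d, ev): float(l) for d, ev, l in zip(drugs, events, lam)}
    return SimulatedReportSet(reports, true_lambda, prior)


def simulate_dated_reports(
    prior: MixturePrior,
    n_drugs: int,
    n_events: int,
    margins: float,
    quarters: Sequence[str],
    seed: int,
    signal_cell: tuple[str, str] | None = None,
    signal_multiplier: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Quarterly report stream for cumulative EBGM studies.

    Background cells keep a fixed lambda drawn once from the prior; the
    optional signal cell has base lambda 1 scaled linearly from
    ``signal_multiplier[0]`` to ``signal_multiplier[1]`` across the quarters
    (a flat (1, 1) multiplier is the no-signal null).  Per-quarter expected
    counts are ``margins / len(quarters)`` per cell.
    """
    prior.validate()
    if margins <= 0:
        raise ValueError("margins must be > 0")
    rng = np.random.default_rng(seed)
    n_cells = n_drugs * n_events
    drugs = np.repeat([f"D{i:03d}" for i in range(n_drugs)], n_events)
    events = np.tile([f"PT9{j:03d}" for j in range(n_events)], n_drugs)
    lam = _draw_lambda(prior, n_cells, rng)
    sig_idx = None
    if signal_cell is not None:
        mask = (drugs == signal_cell[0]) & (events == signal_cell[1])
        if not mask.any():
            raise ValueError(f"signal cell {signal_cell} outside the grid")
        sig_idx = int(np.flatnonzero(mask)[0])
        lam[sig_idx] = 1.0

    e_q = margins / len(quarters)
    rows = []
    m0, m1 = signal_multiplier
    for qi, q in enumerate(quarters):
        frac = qi / (len(quarters) - 1) if len(quarters) > 1 else 0.0
        lam_q = lam.copy()
        if sig_idx is not None:
            lam_q[sig_idx] = lam[sig_idx] * (m0 + frac * (m1 - m0))
        counts = rng.poisson(lam_q * e_q)
        rows.append(pd.DataFrame({
            "drug": drugs, "event_pt": events, "quarter": q, "count": counts,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Sidecar I/O
# ---------------------------------------------------------------------------

def ground_truth_to_json(truth: GroundTruth) -> dict:
    return {
        "posts": {
            pid: {
                "is_duplicate_of": t.is_duplicate_of,
                "is_spam": t.is_spam,
                "is_relevant": t.is_relevant,
                "drugs": sorted(t.drugs),
                "inserted_names": list(t.inserted_names),
                "true_pt_mentions": sorted(t.true_pt_mentions),
            }
            for pid, t in truth.posts.items()
        },
        "planted_probability": [
            {"drug": d, "pt_code": pt, "quarter": q, "p": p}
            for (d, pt, q), p in sorted(truth.planted_probability.items())
        ],
    }
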