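"""Forum-post preprocessing chain: unify, deduplicate, de-spam, relevance-filter, PII-mask.

The chain mirrors the standard social-media pharmacovigilance intake flow:
exact duplicates (same content, poster, and timestamp) are collapsed first,
commercial/spam posts are dropped by keyword lexicon, posts are kept only if
they mention a monitored drug by generic name, brand name, or drug class, and
person names are masked before any downstream analysis.  No stage other than
masking ever edits post text.
"""
from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, ConfigDict, field_validator

from ._text import ensure_utc, phrase_regex

logger = logging.getLogger(__name__)

MASK_TOKEN = "[NAME]"


class ConfigurationError(ValueError):
    """A pipeline stage was configured with unusable inputs."""


class Post(BaseModel):
    """One forum message with provenance metadata."""

    model_config = ConfigDict(frozen=True)

    forum: str
    post_id: str
    thread_id: str
    author_id: str
    timestamp: datetime
    text: str

    @field_validator("timestamp")
    @classmethod
    def _utc(cls, v: datetime) -> datetime:
        return ensure_utc(v)


class ProvenanceFlags(BaseModel):
    model_config = ConfigDict(frozen=True)

    deduped_survivor: bool = True
    spam: bool = False
    relevant: bool = True


class CleanPost(Post):
    """A post that survived the intake chain, with masked text and drug tags."""

    masked_text: str
    drug_mentions: frozenset[str]
    provenance_flags: ProvenanceFlags = ProvenanceFlags()

    @field_validator("drug_mentions")
    @classmethod
    def _nonempty(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("relevance filter guarantees >=1 drug mention")
        return v


def _dedup_key(post: Post) -> tuple[str, str, datetime]:
    # NFC normalization removes encoding noise only; the key itself is exact.
    return (unicodedata.normalize("NFC", post.text), post.author_id, post.timestamp)


def remove_duplicates(posts: Iterable[Post]) -> list[Post]:
    """Collapse posts with identical (content, poster, timestamp).

    The survivor within each duplicate group is the post with the
    lexicographically smallest post_id; survivor input order is preserved.
    """
    posts = list(posts)
    survivor_id: dict[tuple, str] = {}
    for p in posts:
        k = _dedup_key(p)
        if k not in survivor_id or p.post_id < survivor_id[k]:
            survivor_id[k] = p.post_id
    kept = [p for p in posts if survivor_id[_dedup_key(p)] == p.post_id]
    logger.info("dedup: %d in, %d kept", len(posts), len(kept))
    return kept


def remove_spam(posts: Iterable[Post], spam_lexicon: Sequence[str]) -> list[Post]:
    """Drop posts whose text contains any lexicon phrase on word boundaries."""
    lexicon = [s for s in spam_lexicon if s.strip()]
    if not lexicon:
        raise ConfigurationError("spam lexicon is empty; a silent no-op is disallowed")
    patterns = [phrase_regex(s) for s in lexicon]
    posts = list(posts)
    kept = [p for p in posts if not any(pat.search(p.text) for pat in patterns)]
    logger.info("spam: %d in, %d kept", len(posts), len(kept))
    return kept


def _lexicon_keywords(lexicon: Mapping[str, Iterable[str]] | Iterable[str]) -> list[str]:
    if isinstance(lexicon, Mapping):
        out: list[str] = []
        for kws in lexicon.values():
            out.extend(kws)
        return out
    return list(lexicon)


def filter_relevant(
    posts: Iterable[Post],
    drug_lexicons: Mapping[str, Mapping[str, Iterable[str]] | Iterable[str]],
) -> list[CleanPost]:
    """Keep posts mentioning >=1 drug by generic/brand/class keyword.

    ``drug_lexicons`` maps a drug id to its keyword sets (either a flat list
    or a mapping of keyword-kind -> list).  Every matched drug id is recorded
    in ``drug_mentions``.
    """
    compiled: dict[str, list[re.Pattern[str]]] = {}
    for drug, lex in drug_lexicons.items():
        kws = _lexicon_keywords(lex)
        if not kws:
            raise ConfigurationError(f"drug lexicon for {drug!r} has no keywords")
        compiled[drug] = [phrase_regex(k) for k in kws]

    posts = list(posts)
    out: list[CleanPost] = []
    for p in posts:
        hits = frozenset(
            drug for drug, pats in compiled.items() if any(pat.search(p.text) for pat in pats)
        )
        if hits:
            out.append(
                CleanPost(
                    **p.model_dump(),
                    masked_text=p.text,
                    drug_mentions=hits,
                )
            )
    logger.info("relevance: %d in, %d kept", len(posts), len(out))
    return out


class NameMasker:
    """Replaces dictionary person names by the fixed token ``[NAME]``.

    The literal word "name" is excluded from the dictionary so that masking
    is idempotent ("[NAME]" can never re-match).
    """

    def __init__(self, name_dictionary: Iterable[str]):
        names = sorted(
            {n.strip().lower() for n in name_dictionary if n.strip() and n.strip().lower() != "name"},
            key=lambda s: (-len(s), s),
        )
        if not names:
            raise ConfigurationError("name dictionary is empty")
        alt = "|".join(re.escape(n) for n in names)
        self._pattern = re.compile(rf"(?<![0-9A-Za-z])(?:{alt})(?![0-9A-Za-z])", re.IGNORECASE)

    def mask(self, text: str) -> str:
        return self._pattern.sub(MASK_TOKEN, text)


def mask_pii(post: Post, name_dictionary: Iterable[str] | NameMasker) -> Post:
    """Return a copy of the post with person names masked.

    For a :class:`CleanPost` the mask is applied to ``masked_text`` (the text
    analysed downstream); for a raw :class:`Post`, to ``text``.
    """
    masker = name_dictionary if isinstance(name_dictionary, NameMasker) else NameMasker(name_dictionary)
    if isinstance(post, CleanPost):
        return post.model_copy(update={"masked_text": masker.mask(post.masked_text)})
    return post.model_copy(update={"text": masker.mask(post.text)})


@dataclass(frozen=True)
class PipelineResult:
    """Output of the full intake chain with per-stage removal accounting."""

    posts: list[CleanPost]
    n_input: int
    n_duplicates_removed: int
    n_spam_removed: int
    n_irrelevant_removed: int

    @property
    def n_kept(self) -> int:
        return len(self.posts)

    @property
    def conserved(self) -> bool:
        return self.n_input == (
            self.n_kept
            + self.n_duplicates_removed
            + self.n_spam_removed
            + self.n_irrelevant_removed
        )


def run_pipeline(
    posts: Iterable[Post],
    spam_lexicon: Sequence[str],
    drug_lexicons: Mapping[str, Mapping[str, Iterable[str]] | Iterable[str]],
    name_dictionary: Iterable[str],
) -> PipelineResult:
    """Run dedup -> spam -> relevance -> mask, logging removal counts."""
    posts = list(posts)
    deduped = remove_duplicates(posts)
    despammed = remove_spam(deduped, spam_lexicon)
    relevant = filter_relevant(despammed, drug_lexicons)
    masker = NameMasker(name_dictionary)
    masked = [mask_pii(p, masker) for p in relevant]
    return PipelineResult(
        posts=masked,
        n_input=len(posts),
        n_duplicates_removed=len(posts) - len(deduped),
        n_spam_removed=len(deduped) - len(despammed),
        n_irrelevant_removed=len(despammed) - len(relevant),
    )


# ---------------------------------------------------------------------------
# I/O: JSONL posts, plain-text word lists ("#" comments).
# ---------------------------------------------------------------------------

def read_posts_jsonl(path: str | Path) -> list[Post]:
    """Read posts; records carrying ``masked_text`` round-trip as CleanPost."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                cls = CleanPost if "masked_text" in rec else Post
                out.append(cls.model_validate(rec))
    return out


def write_posts_jsonl(posts: Iterable[Post], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            rec = p.model_dump(mode="json")
            if "drug_mentions" in rec:
                rec["drug_mentions"] = sorted(rec["drug_mentions"])
            fh.write(json.dumps(rec) + "\n")


def load_wordlist(path: str | Path) -> list[str]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            entry = line.strip()
            if entry and not entry.startswith("#"):
                out.append(entry)
    return out
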