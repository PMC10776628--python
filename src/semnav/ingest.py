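"""Parsing and preprocessing of coded property-listing transcripts.

A transcript is a delimited UTF-8 text file with one row per listed
property.  Each row carries the participant, their group, the cued
concept, the 1-based production order of the property, the raw property
text and a human-assigned validity tag.  Optionally rows carry
pre-tokenized ``lemma_seq`` / ``pos_seq`` columns (semicolon-joined), in
which case the tagger is bypassed.

Validity coding is a human judgment made upstream; this module only
consumes the assigned tags.  Non-valid responses (statements directed to
the examiner, personal life experiences, metacognitive comments) are
excluded; repetitions and factually incorrect but on-task properties are
coded valid and retained.
"""

from __future__ import annotations

import csv
import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

GROUPS = ("PD", "bvFTD", "HC")
VALIDITY_TAGS = ("valid", "examiner_directed", "personal_experience", "metacognitive")
CONTENT_POS = ("noun", "verb", "adjective", "adverb")

REQUIRED_COLUMNS = ("participant_id", "group", "concept", "property_index", "text", "validity_tag")

#: Coarse tagset -> 4-class content set.  Proper nouns count as nouns;
#: anything mapping to None is a function word and is dropped.
POS_MAP = {
    "noun": "noun",
    "propn": "noun",
    "proper_noun": "noun",
    "verb": "verb",
    "aux": None,
    "adj": "adjective",
    "adjective": "adjective",
    "adv": "adverb",
    "adverb": "adverb",
    "det": None,
    "pron": None,
    "adp": None,
    "cconj": None,
    "sconj": None,
    "part": None,
    "intj": None,
    "num": None,
    "punct": None,
    "sym": None,
    "x": None,
}

_WORD_RE = re.compile(r"[^\W\d_]+(?:-[^\W\d_]+)*", re.UNICODE)


class SchemaError(ValueError):
    """A required transcript column is missing."""


class ValidationError(ValueError):
    """Rows violate the transcript contract (bad group or validity tag)."""


@dataclass(frozen=True)
class ContentToken:
    """A lemmatized content word (noun, verb, adjective or adverb)."""

    surface: str
    lemma: str
    pos: str

    def __post_init__(self) -> None:
        if not self.lemma:
            raise ValueError("lemma must be non-empty")
        if self.pos not in CONTENT_POS:
            raise ValueError(f"pos must be one of {CONTENT_POS}, got {self.pos!r}")


@dataclass(frozen=True)
class PropertyRecord:
    """One listed property for one concept by one participant."""

    participant_id: str
    group: str
    concept: str
    property_index: int
    text: str
    validity_tag: str
    tokens: tuple[ContentToken, ...] = field(default_factory=tuple)
    pretagged: bool = False

    def __post_init__(self) -> None:
        if self.validity_tag not in VALIDITY_TAGS:
            raise ValueError(f"validity_tag must be one of {VALIDITY_TAGS}, got {self.validity_tag!r}")


#: A tagger maps a surface token to (lemma, coarse POS) or None for
#: tokens it cannot analyze.  POS labels are normalized through POS_MAP.
Tagger = Callable[[str], Optional[tuple[str, str]]]


def casefold_lemma(lemma: str) -> str:
    """Case-fold a lemma while preserving accents (Spanish norms are accent-sensitive)."""
    return unicodedata.normalize("NFC", lemma).casefold()


def tokenize_words(text: str) -> list[str]:
    """Split on Unicode word boundaries; hyphenated forms stay one token."""
    return _WORD_RE.findall(text)


def _sniff_delimiter(path: Path, dialect: Optional[str]) -> str:
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t"):
        return "\t"
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def parse_responses(path: str | Path, dialect: Optional[str] = None) -> list[PropertyRecord]:
    """Parse a coded transcript file into PropertyRecords.

    Parameters
    ----------
    path
        Delimited UTF-8 file with the required columns
        (participant_id, group, concept, property_index, text,
        validity_tag) and optional lemma_seq / pos_seq columns.
    dialect
        "csv", "tsv" or None to sniff from the header line.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ValidationError
        if any row carries an unknown group or validity tag; the message
        lists the offending row numbers.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, dialect)
    records: list[PropertyRecord] = []
    bad_rows: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise SchemaError(f"transcript is missing required column {col!r}")
        pretagged_cols = "lemma_seq" in header and "pos_seq" in header
        for lineno, row in enumerate(reader, start=2):
            group = row["group"].strip()
            tag = row["validity_tag"].strip()
            if group not in GROUPS:
                bad_rows.append(f"row {lineno}: unknown group {group!r}")
                continue
            if tag not in VALIDITY_TAGS:
                bad_rows.append(f"row {lineno}: unknown validity_tag {tag!r}")
                continue
            tokens: tuple[ContentToken, ...] = ()
            pretagged = False
            if pretagged_cols and (row.get("lemma_seq") or "").strip():
                lemmas = row["lemma_seq"].split(";")
                poses = (row.get("pos_seq") or "").split(";")
                if len(lemmas) != len(poses):
                    bad_rows.append(f"row {lineno}: lemma_seq/pos_seq length mismatch")
                    continue
                tok_list = []
                for l, p in zip(lemmas, poses):
                    p_norm = POS_MAP.get(p.strip().lower(), p.strip().lower())
                    if p_norm not in CONTENT_POS:
                        continue  # function word slipped into a pre-tagged row
                    tok_list.append(ContentToken(surface=l, lemma=casefold_lemma(l), pos=p_norm))
                tokens = tuple(tok_list)
                pretagged = True
            records.append(
                PropertyRecord(
                    participant_id=row["participant_id"].strip(),
                    group=group,
                    concept=row["concept"].strip(),
                    property_index=int(row["property_index"]),
                    text=row["text"],
                    validity_tag=tag,
                    tokens=tokens,
                    pretagged=pretagged,
                )
            )
    if bad_rows:
        raise ValidationError("invalid transcript rows:\n" + "\n".join(bad_rows))
    return records


def filter_valid(records: Sequence[PropertyRecord]) -> tuple[list[PropertyRecord], dict[str, int]]:
    """Drop non-valid responses, keeping per-tag exclusion counts.

    Repetitions and incorrect-but-on-task properties carry the ``valid``
    tag and are retained.  Returns ``(retained, excluded_counts)`` where
    the counts are keyed by the non-valid tags.
    """
    retained = [r for r in records if r.validity_tag == "valid"]
    excluded = Counter(r.validity_tag for r in records if r.validity_tag != "valid")
    counts = {tag: excluded.get(tag, 0) for tag in VALIDITY_TAGS if tag != "valid"}
    for tag, n in counts.items():
        if n:
            logger.info("filter_valid: excluded %d records tagged %s", n, tag)
    return retained, counts


def extract_content_tokens(record: PropertyRecord, tagger: Tagger) -> PropertyRecord:
    """Populate a record's tokens with lemmatized content words.

    Words are tokenized on Unicode boundaries, passed through ``tagger``
    and kept only when the (normalized) POS is noun, verb, adjective or
    adverb, in surface order.  Pre-tagged records pass through untouched.
    A tagger failure on a token skips that token with a warning.
    """
    if record.pretagged:
        return record
    tokens: list[ContentToken] = []
    for word in tokenize_words(record.text):
        try:
            tagged = tagger(word)
        except Exception:  # tagger failure must never abort the pipeline
            logger.warning("tagger failed on token %r; skipped", word)
            continue
        if tagged is None:
            continue
        lemma, pos = tagged
        pos_norm = POS_MAP.get(pos.lower(), pos.lower() if pos.lower() in CONTENT_POS else None)
        if pos_norm is None:
            continue
        tokens.append(ContentToken(surface=word, lemma=casefold_lemma(lemma), pos=pos_norm))
    return replace(record, tokens=tuple(tokens))


def write_records(records: Iterable[PropertyRecord], path: str | Path, dialect: str = "csv") -> None:
    """Write records back to the canonical delimited format (round-trippable)."""
    delim = "," if dialect == "csv" else "\t"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(list(REQUIRED_COLUMNS) + ["lemma_seq", "pos_seq"])
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.group,
                    r.concept,
                    r.property_index,
                    r.text,
                    r.validity_tag,
                    ";".join(t.lemma for t in r.tokens),
                    ";".join(t.pos for t in r.tokens),
                ]
            )
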