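"""Regex triage of clinical free-text documents.

A document passes through: optional decoding (reports are often stored
base64- or HTML-encoded) → optional header stripping (everything before a
known keyword such as "Findings" is boilerplate) → sentence segmentation →
per-sentence matching of a main pattern, minus sentences that also match an
exclusion pattern.  The classic use: main pattern ``sarcoma`` with exclusion
``osteosarcoma`` keeps "Evidence of sarcoma." and drops "Known osteosarcoma."

The sentence splitter is rule-based and deterministic: boundaries at
terminal punctuation followed by whitespace and a capital letter or digit,
with a configurable abbreviation list (``Dr.``, ``e.g.`` ...) and an
implicit decimal-number exception ("a 3.5 cm mass" never splits).  A
different segmentation engine (e.g. a statistical model) can be plugged in
via ``sentence_splitter``.
"""

from __future__ import annotations

import logging
import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

from .errors import SkiffError

logger = logging.getLogger(__name__)

DEFAULT_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "st", "jr", "sr",
        "vs", "etc", "approx", "ca", "cf", "resp",
        "e.g", "i.e", "fig", "no", "pt", "dx", "hx",
    }
)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=(\s+)[\"'(]?[A-Z0-9])")
_TRAILING_WORD_RE = re.compile(r"([A-Za-z][A-Za-z.]*)$")


def split_sentences(
    text: str,
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
) -> list[str]:
    """Deterministic sentence segmentation.

    The concatenation of the returned sentences reproduces the input text
    modulo boundary whitespace.
    """
    if not text or not text.strip():
        return []
    boundaries: list[int] = []
    for match in _BOUNDARY_RE.finditer(text):
        word = _TRAILING_WORD_RE.search(text, 0, match.start())
        if word:
            token = word.group(1).rstrip(".").lower()
            if token in abbreviations or (len(token) == 1 and token.isalpha()):
                continue
        boundaries.append(match.end())
    sentences: list[str] = []
    start = 0
    for end in boundaries:
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def strip_header(text: str, keyword: str) -> str:
    """Drop everything before the first occurrence of ``keyword`` (inclusive).

    If the keyword is absent the text is returned unchanged and the document
    is flagged via a log warning.  Idempotent: a second application is a
    no-op because the keyword then sits at position 0.
    """
    if not keyword:
        raise SkiffError("header keyword must be non-empty")
    pos = text.find(keyword)
    if pos < 0:
        logger.warning("header keyword %r not found in document", keyword)
        return text
    return text[pos:]


@dataclass
class MinerConfig:
    """Patterns and preprocessing for one mining run."""

    main_pattern: str
    exclusion_pattern: str | None = None
    header_keyword: str | None = None
    case_insensitive: bool = True
    text_column: str = "text"
    decode_fn: Callable[[object], str] | None = None
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
    sentence_splitter: Callable[[str], list[str]] | None = None

    def __post_init__(self) -> None:
        flags = re.IGNORECASE if self.case_insensitive else 0
        try:
            self._main = re.compile(self.main_pattern, flags)
        except re.error as exc:
            raise SkiffError(f"main_pattern does not compile: {exc}") from exc
        self._exclusion = None
        if self.exclusion_pattern is not None:
            try:
                self._exclusion = re.compile(self.exclusion_pattern, flags)
            except re.error as exc:
                raise SkiffError(f"exclusion_pattern does not compile: {exc}") from exc

    def _split(self, text: str) -> list[str]:
        if self.sentence_splitter is not None:
            return self.sentence_splitter(text)
        return split_sentences(text, self.abbreviations)


@dataclass
class DocReport:
    """Per-document mining summary.

    ``matched`` holds iff at least one sentence matches the main pattern and
    not the exclusion pattern; ``match_count`` equals the number of such
    sentences; ``excluded_count`` counts sentences dropped by the exclusion.
    """

    matched: bool
    matching_sentences: list[str] = field(default_factory=list)
    match_count: int = 0
    excluded_count: int = 0


def mine_text(text: object, config: MinerConfig) -> DocReport:
    """Run the full triage pipeline on one document."""
    if config.decode_fn is not None:
        try:
            text = config.decode_fn(text)
        except Exception as exc:
            raise SkiffError(f"decode_fn failed: {exc}") from exc
    if text is None:
        text = ""
    if not isinstance(text, str):
        text = str(text)
    if config.header_keyword:
        text = strip_header(text, config.header_keyword)
    matching: list[str] = []
    excluded = 0
    for sentence in config._split(text):
        if not config._main.search(sentence):
            continue
        if config._exclusion is not None and config._exclusion.search(sentence):
            excluded += 1
            continue
        matching.append(sentence)
    return DocReport(
        matched=bool(matching),
        matching_sentences=matching,
        match_count=len(matching),
        excluded_count=excluded,
    )


def nlp_on_dataframe(
    table: pd.DataFrame,
    config: MinerConfig,
    n_procs: int = 1,
) -> pd.DataFrame:
    """Mine every row's text cell; append the report as four columns.

    Appends ``matched`` / ``matching_sentences`` / ``match_count`` /
    ``excluded_count``.  Rows with a missing text cell get a missing
    ``matched``.  Output is identical for any ``n_procs``.
    """
    if config.text_column not in table.columns:
        raise KeyError(config.text_column)
    texts = [table[config.text_column].iloc[pos] for pos in range(len(table))]

    def mine_one(raw):
        if raw is None or (not isinstance(raw, (list, dict)) and pd.isna(raw)):
            return None
        return mine_text(raw, config)

    if n_procs > 1 and len(texts) > 1:
        with ThreadPoolExecutor(max_workers=n_procs) as pool:
            reports = list(pool.map(mine_one, texts))
    else:
        reports = [mine_one(raw) for raw in texts]

    out = table.copy()
    out["matched"] = pd.array(
        [None if r is None else r.matched for r in reports], dtype=object
    )
    out["matching_sentences"] = pd.array(
        [None if r is None else r.matching_sentences for r in reports], dtype=object
    )
    out["match_count"] = pd.array(
        [None if r is None else r.match_count for r in reports], dtype=object
    )
    out["excluded_count"] = pd.array(
        [None if r is None else r.excluded_count for r in reports], dtype=object
    )
    return out
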