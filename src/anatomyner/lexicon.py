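"""Gazetteer compilation and matching.

Two dictionaries drive the gazetteer features: an anatomy dictionary
(Dictionary-1, merged from several term resources with per-source
provenance) and a closed list of positional modifiers (Dictionary-2,
"left", "bilateral", "distal", ...).  Matching returns every n-gram of a
sentence whose normalized tokens equal a lexicon entry — overlaps
included — because the downstream feature is per-token membership, not a
segmentation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

logger = logging.getLogger(__name__)

_EDGE_PUNCT = ".,;:!?()[]{}\"'`"


def normalize_term(raw: str) -> tuple[str, ...]:
    """Lowercase, collapse whitespace, strip punctuation at token edges.

    Idempotent; returns an empty tuple if nothing survives (callers warn
    and drop such terms).
    """
    tokens = []
    for chunk in raw.lower().split():
        chunk = chunk.strip(_EDGE_PUNCT)
        if chunk:
            tokens.append(chunk)
    return tuple(tokens)


@dataclass(frozen=True)
class MatchSpan:
    sentence_index: int
    start: int
    end: int
    entry: tuple[str, ...]


@dataclass
class Lexicon:
    """A set of normalized multi-word entries with source provenance."""

    name: str = "lexicon"
    entries: set[tuple[str, ...]] = field(default_factory=set)
    provenance: dict[tuple[str, ...], set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term) -> bool:
        return tuple(term) in self.entries

    @property
    def max_entry_length(self) -> int:
        return max((len(e) for e in self.entries), default=0)

    # -- matching ----------------------------------------------------------

    def match(
        self,
        sentence: list[str],
        sentence_index: int = 0,
        max_len: int | None = None,
    ) -> list[MatchSpan]:
        """All n-gram matches (1 <= n <= max_len), overlapping included.

        A token that normalizes to nothing (pure punctuation) acts as a
        boundary: no match window contains it, so dictionary-membership
        flags never mark punctuation.
        """
        if max_len is None:
            max_len = self.max_entry_length
        norm = [normalize_term(tok) for tok in sentence]
        out: list[MatchSpan] = []
        n = len(sentence)
        for start in range(n):
            gram: list[str] = []
            end = start
            while end < n and len(gram) < max_len:
                if not norm[end]:
                    break
                gram.extend(norm[end])
                end += 1
                if len(gram) > max_len:
                    break
                key = tuple(gram)
                if key in self.entries:
                    out.append(MatchSpan(sentence_index, start, end, key))
        return out

    def membership_flags(self, sentence: list[str]) -> list[int]:
        """Per-token 0/1 vector: 1 iff some match covers the token."""
        return membership_flags(self.match(sentence), len(sentence))

    # -- persistence -------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "entries": sorted(
                {
                    " ".join(entry): sorted(self.provenance.get(entry, set()))
                    for entry in self.entries
                }.items()
            ),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Lexicon":
        lex = cls(name=obj.get("name", "lexicon"))
        for term, sources in obj["entries"]:
            entry = tuple(term.split())
            lex.entries.add(entry)
            lex.provenance[entry] = set(sources)
        return lex

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, sort_keys=True, indent=0)

    @classmethod
    def load(cls, path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def membership_flags(matches: list[MatchSpan], sentence_length: int) -> list[int]:
    flags = [0] * sentence_length
    for m in matches:
        for i in range(m.start, min(m.end, sentence_length)):
            flags[i] = 1
    return flags


def compile_lexicon(
    sources: dict[str, list[str]], name: str = "lexicon"
) -> Lexicon:
    """Union normalized terms from several sources, recording provenance.

    Duplicate entries (within or across sources) collapse to one; terms
    that normalize to nothing are dropped with a warning.
    """
    if not sources:
        raise ValueError("at least one source is required")
    lex = Lexicon(name=name)
    for source_name, terms in sources.items():
        for raw in terms:
            entry = normalize_term(raw)
            if not entry:
                logger.warning(
                    "%s: term %r from source %r normalizes to empty; dropped",
                    name,
                    raw,
                    source_name,
                )
                continue
            lex.entries.add(entry)
            lex.provenance.setdefault(entry, set()).add(source_name)
    if not lex.entries:
        raise ValueError(f"{name}: no usable entries in any source")
    return lex


def read_term_list(path) -> list[str]:
    """One term per line, UTF-8, '#' comments and blank lines ignored."""
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                terms.append(line)
    return terms


def bundled_position_lexicon() -> Lexicon:
    """The bundled positional-modifier dictionary (Dictionary-2 stand-in)."""
    text = (
        resources.files("anatomyner").joinpath("data/positions.txt").read_text("utf-8")
    )
    terms = [
        ln.split("#", 1)[0].strip() for ln in text.splitlines()
    ]
    return compile_lexicon(
        {"bundled": [t for t in terms if t]}, name="Dictionary-2"
    )


def coverage(
    lexicon: Lexicon, docs, label: str = "explicit"
) -> tuple[int, int, float | None]:
    """Gazetteer coverage of gold anatomy tokens.

    A gold token counts as matched iff its dictionary membership flag is 1.
    Returns ``(matched_tokens, total_tokens, percentage)``; the percentage
    is ``None`` when the corpus has no gold tokens of the class.
    """
    matched = 0
    total = 0
    for doc in docs:
        spans = [sp for sp in doc.anatomy_spans if sp.label == label]
        by_sentence: dict[int, list] = {}
        for sp in spans:
            by_sentence.setdefault(sp.sentence_index, []).append(sp)
        for s, sent_spans in by_sentence.items():
            flags = lexicon.membership_flags(doc.sentences[s])
            for sp in sent_spans:
                for i in range(sp.start, sp.end):
                    total += 1
                    matched += flags[i]
    if total == 0:
        return (0, 0, None)
    return (matched, total, coverage_percent(matched, total))


def coverage_percent(matched: int, total: int) -> float:
    """Coverage as a percentage rounded half-even to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * matched / total, 2)
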