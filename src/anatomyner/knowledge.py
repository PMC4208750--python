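"""Offline knowledge-base snapshots and world-knowledge features.

Live encyclopedia/lexical-database access is replaced by immutable
JSON-lines snapshot files mapping a normalized term to its definition
text.  For an ``encyclopedia`` snapshot only the first three sentences of
the stored text count as the definition; for a ``lexical`` snapshot
(a WordNet-style gloss source) the full text counts.

Three binary per-token features derive from the snapshots:

WF1
    For every non-stopword token taken alone: 1 iff the token has an
    entry whose effective definition mentions an anatomy-dictionary term.
WF2
    For every medical-concept span (disease/test/treatment): look up the
    whole span text in the encyclopedia snapshot; if its effective
    definition mentions anatomy, all tokens of the span get 1.
WF3
    As WF2, but against the lexical snapshot with full-gloss definitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .corpus_io import EntitySpan, split_sentences, tokenize
from .lexicon import Lexicon, normalize_term

SNAPSHOT_KINDS = ("encyclopedia", "lexical")


@dataclass
class KnowledgeSnapshot:
    """Immutable term -> definition map with a kind-dependent truncation."""

    kind: str
    entries: dict[tuple[str, ...], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SNAPSHOT_KINDS:
            raise ValueError(
                f"snapshot kind must be one of {SNAPSHOT_KINDS}, got {self.kind!r}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, term: str, definition: str) -> None:
        key = normalize_term(term)
        if key:
            self.entries[key] = definition

    def effective_definition(self, term) -> str | None:
        """Definition text used by the features, or None if absent.

        Encyclopedia entries are truncated to their first three
        sentences; lexical entries are returned in full.
        """
        text = self.entries.get(tuple(term))
        if text is None:
            return None
        if self.kind == "encyclopedia":
            return " ".join(split_sentences(text)[:3])
        return text

    # -- persistence: JSON-lines with a header record declaring the kind --

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"kind": self.kind}) + "\n")
            for term in sorted(self.entries):
                fh.write(
                    json.dumps(
                        {"term": " ".join(term), "definition": self.entries[term]},
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, path) -> "KnowledgeSnapshot":
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            snap = cls(kind=header["kind"])
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    snap.add(rec["term"], rec["definition"])
        return snap


def definition_mentions_anatomy(definition: str, dict1: Lexicon) -> bool:
    """True iff the definition text contains an anatomy-dictionary term."""
    tokens = tokenize(definition)
    return bool(dict1.match(tokens))


def load_stopwords() -> frozenset[str]:
    text = (
        resources.files("anatomyner").joinpath("data/stopwords.txt").read_text("utf-8")
    )
    words = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return frozenset(words)


def compute_wf1(
    sentence: list[str],
    stopwords: frozenset[str],
    snapshot: KnowledgeSnapshot,
    dict1: Lexicon,
) -> list[int]:
    """Per-word knowledge flag, independent of the concept layer."""
    flags = [0] * len(sentence)
    for i, token in enumerate(sentence):
        if token.lower() in stopwords:
            continue
        key = normalize_term(token)
        if not key:
            continue
        defn = snapshot.effective_definition(key)
        if defn is not None and definition_mentions_anatomy(defn, dict1):
            flags[i] = 1
    return flags


def _concept_flags(
    concept_spans: list[EntitySpan],
    sentences: list[list[str]],
    snapshot: KnowledgeSnapshot,
    dict1: Lexicon,
) -> list[list[int]]:
    flags = [[0] * len(s) for s in sentences]
    for sp in concept_spans:
        tokens = sentences[sp.sentence_index][sp.start : sp.end]
        key = normalize_term(" ".join(tokens))
        defn = snapshot.effective_definition(key)
        if defn is not None and definition_mentions_anatomy(defn, dict1):
            for i in range(sp.start, sp.end):
                flags[sp.sentence_index][i] = 1
    return flags


def compute_wf2(
    concept_spans: list[EntitySpan],
    sentences: list[list[str]],
    snapshot_encyclopedia: KnowledgeSnapshot,
    dict1: Lexicon,
) -> list[list[int]]:
    """Concept-level flag from encyclopedia definitions (first 3 sentences)."""
    if snapshot_encyclopedia.kind != "encyclopedia":
        raise ValueError("WF2 requires an encyclopedia snapshot")
    return _concept_flags(concept_spans, sentences, snapshot_encyclopedia, dict1)


def compute_wf3(
    concept_spans: list[EntitySpan],
    sentences: list[list[str]],
    snapshot_lexical: KnowledgeSnapshot,
    dict1: Lexicon,
) -> list[list[int]]:
    """Concept-level flag from full lexical-database glosses."""
    if snapshot_lexical.kind != "lexical":
        raise ValueError("WF3 requires a lexical snapshot")
    return _concept_flags(concept_spans, sentences, snapshot_lexical, dict1)
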