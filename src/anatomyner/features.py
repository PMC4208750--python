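"""Per-token feature extraction for the CRF layers.

Every token of a sentence gets a named-feature mapping combining:

* baseline orthographic features — the token itself, capitalization
  flags, a shape-normalized form (lowercase with digit runs folded to
  ``#``), character prefixes/suffixes of lengths 1–8, optional POS tags
  from up to two pluggable providers, and the covering medical-concept
  class (``ConceptType``);
* gazetteer features DF1 (anatomy dictionary) and DF2 (positional
  modifiers);
* the coreference feature CF, which propagates anatomical status across
  a coreference chain (full form -> local abbreviation);
* world-knowledge features WF1/WF2/WF3 (see :mod:`anatomyner.knowledge`);
* the hierarchical feature HF, filled in by the pipeline for the
  implicit layer only.

Feature extraction is pure: the same document and configuration yield a
byte-identical table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .corpus_io import Document, EntitySpan
from .knowledge import KnowledgeSnapshot, compute_wf1, compute_wf2, compute_wf3, load_stopwords
from .lexicon import Lexicon

MAX_AFFIX = 8

FeatureRow = dict[str, str]


# ---------------------------------------------------------------------------
# POS providers


class PosProvider:
    """Tagging contract: token list -> equal-length POS label list."""

    name = "pos"

    def tag(self, sentence: list[str]) -> list[str]:  # pragma: no cover
        raise NotImplementedError


class RulePosTagger(PosProvider):
    """Deterministic rule-based tagger standing in for a full parser.

    Closed-class word lists plus suffix heuristics; everything else is a
    noun.  Accuracy is secondary — the contract is determinism and
    equal-length output.
    """

    name = "rulepos"

    _DET = {"the", "a", "an", "this", "that", "these", "those"}
    _PREP = {"in", "on", "of", "to", "for", "with", "at", "by", "from", "into"}
    _CONJ = {"and", "or", "but"}
    _PRON = {"he", "she", "it", "they", "his", "her", "its", "their", "patient's"}
    _AUX = {"is", "was", "are", "were", "be", "been", "has", "had", "have", "will"}
    _NUM = re.compile(r"^\d+([./]\d+)?$")

    def tag(self, sentence: list[str]) -> list[str]:
        tags = []
        for tok in sentence:
            low = tok.lower()
            if low in self._DET:
                tags.append("DT")
            elif low in self._PREP:
                tags.append("IN")
            elif low in self._CONJ:
                tags.append("CC")
            elif low in self._PRON:
                tags.append("PRP")
            elif low in self._AUX:
                tags.append("VB")
            elif self._NUM.match(low):
                tags.append("CD")
            elif not any(c.isalnum() for c in tok):
                tags.append("PUNCT")
            elif low.endswith("ly"):
                tags.append("RB")
            elif low.endswith(("ed", "ing")):
                tags.append("VBD")
            elif low.endswith(("al", "ic", "ous", "ar", "ive")):
                tags.append("JJ")
            else:
                tags.append("NN")
        return tags


# ---------------------------------------------------------------------------
# Baseline features

_DIGITS = re.compile(r"\d+")


def shape_normalize(token: str) -> str:
    """Lowercase with digit runs folded to '#' ("x4" -> "x#")."""
    return _DIGITS.sub("#", token.lower())


def baseline_features(
    sentence: list[str],
    pos_providers: list[PosProvider] | None = None,
    concept_spans: list[EntitySpan] | None = None,
    sentence_index: int = 0,
) -> list[FeatureRow]:
    """Orthographic + POS + concept-type features for one sentence."""
    pos_providers = pos_providers or []
    if len(pos_providers) > 2:
        raise ValueError("at most two POS providers are supported")
    pos_tags = []
    for provider in pos_providers:
        tags = provider.tag(sentence)
        if len(tags) != len(sentence):
            raise ValueError(
                f"POS provider {provider.name!r} returned {len(tags)} tags "
                f"for {len(sentence)} tokens"
            )
        pos_tags.append(tags)

    concept_type = ["NONE"] * len(sentence)
    for sp in concept_spans or []:
        if sp.sentence_index != sentence_index:
            continue
        for i in range(sp.start, sp.end):
            concept_type[i] = sp.label

    rows: list[FeatureRow] = []
    for i, token in enumerate(sentence):
        alpha = [c for c in token if c.isalpha()]
        # binary flags are emitted only when set; an absent flag carries no
        # weight, so rare indicators do not double as class priors
        row: FeatureRow = {
            "Original": token,
            "Norm": shape_normalize(token),
        }
        if token[:1].isupper():
            row["CapUpper"] = "1"
        if alpha and all(c.isupper() for c in alpha):
            row["AllUpper"] = "1"
        if concept_type[i] != "NONE":
            row["ConceptType"] = concept_type[i]
        for k in range(1, min(MAX_AFFIX, len(token)) + 1):
            row[f"Prefix{k}"] = token[:k]
            row[f"Suffix{k}"] = token[-k:]
        for slot, tags in zip(("POS_A", "POS_B"), pos_tags):
            row[slot] = tags[i]
        rows.append(row)
    return rows


def dictionary_features(
    sentence: list[str], dict1: Lexicon, dict2: Lexicon
) -> tuple[list[int], list[int]]:
    """DF1/DF2 per-token membership flags."""
    return dict1.membership_flags(sentence), dict2.membership_flags(sentence)


def coref_feature(doc: Document, anatomy_indicator) -> list[list[int]]:
    """CF per token: 1 iff the token lies in a mention of a chain that has
    at least one indicator-positive mention.

    ``anatomy_indicator(doc, mention) -> bool`` decides whether a mention
    counts as anatomical; at training time this is gold-span membership,
    at inference time a dictionary-match or explicit-layer predicate.
    """
    flags = [[0] * len(s) for s in doc.sentences]
    for chain in doc.chains:
        if any(anatomy_indicator(doc, m) for m in chain.mentions):
            for m in chain.mentions:
                for i in range(m.start, m.end):
                    flags[m.sentence_index][i] = 1
    return flags


def gold_anatomy_indicator(doc: Document, mention) -> bool:
    """A mention is anatomical iff it coincides with a gold anatomy span."""
    return any(
        sp.sentence_index == mention.sentence_index
        and sp.start == mention.start
        and sp.end == mention.end
        for sp in doc.anatomy_spans
    )


def make_dict_indicator(dict1: Lexicon):
    """Inference-time indicator: the mention text matches Dictionary-1."""

    def indicator(doc: Document, mention) -> bool:
        tokens = doc.sentences[mention.sentence_index][mention.start : mention.end]
        matches = dict1.match(tokens)
        return any(m.start == 0 and m.end == len(tokens) for m in matches)

    return indicator


# ---------------------------------------------------------------------------
# Context-window assembly


def assemble(rows: list[FeatureRow], window: int = 2) -> list[FeatureRow]:
    """Expand each token's features with its neighbours' within ±window.

    Neighbour copies are suffixed with the relative offset
    (``Original[-1]``); positions past the sentence edge contribute
    ``BOS[k]``/``EOS[k]`` padding markers so the schema stays constant.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    n = len(rows)
    out: list[FeatureRow] = []
    for i in range(n):
        row = dict(rows[i])
        for off in range(-window, window + 1):
            if off == 0:
                continue
            j = i + off
            if 0 <= j < n:
                for name, value in rows[j].items():
                    row[f"{name}[{off:+d}]"] = value
            elif j < 0:
                row[f"BOS[{off:+d}]"] = "1"
            else:
                row[f"EOS[{off:+d}]"] = "1"
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# Document-level extraction


@dataclass
class FeatureConfig:
    """Feature toggles and resources shared by the recognizer layers."""

    df1: bool = True
    df2: bool = True
    cf: bool = True
    wf1: bool = True
    wf2: bool = True
    wf3: bool = True
    hf: bool = False
    window: int = 2
    dict1: Lexicon | None = None
    dict2: Lexicon | None = None
    snapshot_encyclopedia: KnowledgeSnapshot | None = None
    snapshot_lexical: KnowledgeSnapshot | None = None
    pos_providers: list[PosProvider] = field(default_factory=lambda: [RulePosTagger()])
    stopwords: frozenset[str] = field(default_factory=load_stopwords)

    def baseline_only(self) -> "FeatureConfig":
        return replace(
            self, df1=False, df2=False, cf=False, wf1=False, wf2=False, wf3=False,
            hf=False,
        )

    def schema_names(self) -> tuple[str, ...]:
        """The feature-name schema this configuration produces.

        Binary flags may be absent from any given row (they are emitted
        only when set), so schema compatibility is defined by the
        configuration, not by observed rows.
        """
        names = ["Original", "Norm", "CapUpper", "AllUpper", "ConceptType"]
        names += [f"Prefix{k}" for k in range(1, MAX_AFFIX + 1)]
        names += [f"Suffix{k}" for k in range(1, MAX_AFFIX + 1)]
        names += [slot for slot, _ in zip(("POS_A", "POS_B"), self.pos_providers)]
        for flag in ("df1", "df2", "cf", "wf1", "wf2", "wf3", "hf"):
            if getattr(self, flag):
                names.append(flag.upper())
        names.append(f"window:{self.window}")
        return tuple(sorted(names))

    def required_resources(self) -> list[str]:
        missing = []
        if self.df1 and self.dict1 is None:
            missing.append("dict1")
        if self.df2 and self.dict2 is None:
            missing.append("dict2")
        if (self.wf1 or self.wf2 or self.hf) and self.snapshot_encyclopedia is None:
            missing.append("snapshot_encyclopedia")
        if self.wf3 and self.snapshot_lexical is None:
            missing.append("snapshot_lexical")
        return missing


def extract_document(
    doc: Document,
    config: FeatureConfig,
    concept_spans: list[EntitySpan] | None = None,
    hf_flags: list[list[int]] | None = None,
    coref_indicator=None,
) -> list[list[FeatureRow]]:
    """Full feature table for a document, one row list per sentence.

    ``concept_spans`` defaults to the document's gold concept layer
    (training mode); the pipeline passes predicted spans at inference.
    ``hf_flags`` is the hierarchical-feature vector computed by the
    pipeline; absent, HF is emitted as 0 when enabled.
    """
    missing = config.required_resources()
    if missing:
        raise ValueError(f"feature config enables features missing resources: {missing}")
    if concept_spans is None:
        concept_spans = doc.concept_spans

    cf_flags = None
    if config.cf:
        indicator = coref_indicator or gold_anatomy_indicator
        cf_flags = coref_feature(doc, indicator)
    wf2_flags = (
        compute_wf2(concept_spans, doc.sentences, config.snapshot_encyclopedia, config.dict1)
        if config.wf2
        else None
    )
    wf3_flags = (
        compute_wf3(concept_spans, doc.sentences, config.snapshot_lexical, config.dict1)
        if config.wf3
        else None
    )

    tables: list[list[FeatureRow]] = []
    for s, sentence in enumerate(doc.sentences):
        sent_concepts = [sp for sp in concept_spans if sp.sentence_index == s]
        rows = baseline_features(
            sentence,
            pos_providers=config.pos_providers,
            concept_spans=sent_concepts,
            sentence_index=s,
        )
        def set_flags(name: str, values: list[int]) -> None:
            for row, v in zip(rows, values):
                if v:
                    row[name] = "1"

        if config.df1:
            set_flags("DF1", config.dict1.membership_flags(sentence))
        if config.df2:
            set_flags("DF2", config.dict2.membership_flags(sentence))
        if cf_flags is not None:
            set_flags("CF", cf_flags[s])
        if config.wf1:
            set_flags(
                "WF1",
                compute_wf1(
                    sentence, config.stopwords, config.snapshot_encyclopedia, config.dict1
                ),
            )
        if wf2_flags is not None:
            set_flags("WF2", wf2_flags[s])
        if wf3_flags is not None:
            set_flags("WF3", wf3_flags[s])
        if config.hf:
            set_flags("HF", hf_flags[s] if hf_flags is not None else [0] * len(sentence))
        tables.append(assemble(rows, window=config.window))
    return tables
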