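"""The three-layer recognizer stack and its orchestration.

Step 1 recognizes medical concepts (diseases, clinical tests and
treatments) with a multi-class BIO CRF — or passes through gold
annotations when configured.  Step 2 recognizes explicit anatomical
entities.  Step 3 recognizes implicit anatomical entities, additionally
using the hierarchical feature (HF): the trained explicit recognizer is
applied to the knowledge-base definition of each Step-1 concept, and if
it finds an explicit entity there, every token of that concept gets
HF = 1.  HF is only ever used by the implicit layer.

Training-time concept-dependent features (ConceptType, WF2, WF3, HF) are
computed from gold concept spans; at inference they come from gold or
predicted concepts depending on ``PipelineConfig.concept_source``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .corpus_io import Document, EntitySpan, bio_to_spans, document_tags, split_sentences, tokenize
from .crf import ChainCRF, SchemaMismatchError, schema_hash
from .features import (
    FeatureConfig,
    extract_document,
    gold_anatomy_indicator,
    make_dict_indicator,
)
from .knowledge import KnowledgeSnapshot
from .lexicon import normalize_term

logger = logging.getLogger(__name__)

LAYERS = ("concepts", "explicit", "implicit")


@dataclass
class PipelineConfig:
    """Everything the hierarchical pipeline needs besides the documents."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    concept_source: str = "gold"  # "gold" | "model"
    overlap_policy: str = "explicit"  # explicit spans win over implicit
    cf_inference: str = "dict1"  # "dict1" | "gold"
    c2: float = 1.0
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concept_source not in ("gold", "model"):
            raise ValueError(f"concept_source must be gold|model, not {self.concept_source!r}")


def _layer_feature_config(config: FeatureConfig, layer: str) -> FeatureConfig:
    """Per-layer view of the feature toggles.

    The concepts layer sees only baseline + gazetteer features (its own
    output would otherwise feed back into it); HF is restricted to the
    implicit layer.
    """
    if layer == "concepts":
        return replace(config, cf=False, wf1=False, wf2=False, wf3=False, hf=False)
    if layer == "explicit":
        return replace(config, hf=False)
    if layer == "implicit":
        return config
    raise ValueError(f"unknown layer {layer!r}")


class LayerTagger(BaseEstimator):
    """One CRF recognizer layer over annotated documents.

    ``layer='explicit' | 'implicit'`` trains a binary B/I/O tagger on the
    anatomy spans of that class; ``layer='concepts'`` trains a
    multi-class ``B-x/I-x/O`` tagger on the concept layer.
    """

    def __init__(
        self,
        layer: str = "explicit",
        config: FeatureConfig | None = None,
        c2: float = 1.0,
        max_iterations: int = 100,
    ):
        self.layer = layer
        self.config = config
        self.c2 = c2
        self.max_iterations = max_iterations

    def _feature_config(self) -> FeatureConfig:
        base = self.config if self.config is not None else FeatureConfig()
        return _layer_feature_config(base, self.layer)

    def _featurize(self, doc: Document, concept_spans=None, hf_flags=None, coref_indicator=None):
        cfg = self._feature_config()
        if self.layer == "concepts":
            concept_spans = []
        return extract_document(
            doc,
            cfg,
            concept_spans=concept_spans,
            hf_flags=hf_flags,
            coref_indicator=coref_indicator,
        )

    def _gold_tags(self, doc: Document) -> list[list[str]]:
        if self.layer == "concepts":
            return document_tags(doc, "concepts")
        return document_tags(doc, "anatomy", label=self.layer)

    def fit(self, docs: list[Document], hf_flags: dict[str, list[list[int]]] | None = None):
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        X, y = [], []
        for doc in docs:
            flags = (hf_flags or {}).get(doc.doc_id)
            X.extend(self._featurize(doc, hf_flags=flags))
            y.extend(self._gold_tags(doc))
        # binary flags appear in rows only when set, so the observed-name
        # check inside ChainCRF would be spurious; schema compatibility is
        # enforced here from the feature configuration instead
        self.schema_ = self._feature_config().schema_names()
        self.schema_hash_ = schema_hash(self.schema_)
        self.crf_ = ChainCRF(
            c2=self.c2, max_iterations=self.max_iterations, check_schema=False
        )
        self.crf_.fit(X, y)
        return self

    def predict_document(
        self, doc: Document, concept_spans=None, hf_flags=None, coref_indicator=None
    ) -> list[EntitySpan]:
        """Predicted spans for one document (lenient BIO decode)."""
        current = self._feature_config().schema_names()
        if hasattr(self, "schema_") and current != self.schema_:
            raise SchemaMismatchError(
                f"feature schema differs from training: "
                f"{sorted(set(current) ^ set(self.schema_))}"
            )
        X = self._featurize(
            doc,
            concept_spans=concept_spans,
            hf_flags=hf_flags,
            coref_indicator=coref_indicator,
        )
        tag_seqs = self.crf_.predict(X)
        default = self.layer if self.layer != "concepts" else "disease"
        spans: list[EntitySpan] = []
        for s, tags in enumerate(tag_seqs):
            spans.extend(bio_to_spans(tags, sentence_index=s, default_label=default))
        return spans

    def predict(self, docs: list[Document]) -> list[list[EntitySpan]]:
        return [self.predict_document(doc) for doc in docs]


# ---------------------------------------------------------------------------
# Hierarchical feature


def _definition_document(term_key: tuple[str, ...], definition: str) -> Document:
    sentences = [tokenize(s) for s in split_sentences(definition)]
    sentences = [s for s in sentences if s]
    return Document(doc_id=f"defn:{' '.join(term_key)}", sentences=sentences)


def _neutral_config(config: FeatureConfig) -> FeatureConfig:
    """Same schema as ``config`` but CF/WF evaluate to 0.

    Definitions are featurized with baseline + DF1/DF2 only; the
    coreference and world-knowledge slots stay in the schema (the
    explicit model expects them) but are neutralized by empty resources.
    """
    empty_e = KnowledgeSnapshot(kind="encyclopedia") if (config.wf1 or config.wf2) else None
    empty_l = KnowledgeSnapshot(kind="lexical") if config.wf3 else None
    return replace(
        config, hf=False, snapshot_encyclopedia=empty_e, snapshot_lexical=empty_l
    )


def hierarchical_feature(
    explicit_tagger: LayerTagger,
    doc: Document,
    concept_spans: list[EntitySpan],
    snapshot_encyclopedia: KnowledgeSnapshot,
    _cache: dict | None = None,
) -> list[list[int]]:
    """HF vector for one document.

    For each concept span: fetch the effective (three-sentence)
    definition of the span text; run the explicit recognizer over it; if
    any explicit entity is predicted, every token of the concept span
    gets 1.  Missing definitions give 0.  Results are cached per term.
    """
    flags = [[0] * len(s) for s in doc.sentences]
    cfg = _neutral_config(explicit_tagger._feature_config())
    probe = LayerTagger(
        layer="explicit",
        config=cfg,
        c2=explicit_tagger.c2,
        max_iterations=explicit_tagger.max_iterations,
    )
    probe.crf_ = explicit_tagger.crf_
    for sp in concept_spans:
        tokens = doc.sentences[sp.sentence_index][sp.start : sp.end]
        key = normalize_term(" ".join(tokens))
        if _cache is not None and key in _cache:
            hit = _cache[key]
        else:
            defn = snapshot_encyclopedia.effective_definition(key)
            if defn is None:
                hit = False
            else:
                mini = _definition_document(key, defn)
                hit = bool(mini.sentences) and bool(probe.predict_document(mini))
            if _cache is not None:
                _cache[key] = hit
        if hit:
            for i in range(sp.start, sp.end):
                flags[sp.sentence_index][i] = 1
    return flags


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineResult:
    doc_id: str
    concept_spans: list[EntitySpan]
    explicit_spans: list[EntitySpan]
    implicit_spans: list[EntitySpan]

    @property
    def anatomy_spans(self) -> list[EntitySpan]:
        return sorted(
            self.explicit_spans + self.implicit_spans,
            key=lambda sp: (sp.sentence_index, sp.start),
        )


class AnatomyPipeline(BaseEstimator):
    """Step 1 -> 2 -> 3 hierarchical anatomical-entity recognizer."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config

    def _config(self) -> PipelineConfig:
        return self.config if self.config is not None else PipelineConfig()

    def fit(self, docs: list[Document]):
        if not docs:
            raise ValueError("cannot fit the pipeline on an empty corpus")
        cfg = self._config()
        fcfg = cfg.features
        missing = fcfg.required_resources()
        if missing:
            raise ValueError(f"pipeline config missing resources: {missing}")

        if cfg.concept_source == "model":
            self.concepts_ = LayerTagger(
                layer="concepts", config=fcfg, c2=cfg.c2,
                max_iterations=cfg.max_iterations,
            ).fit(docs)
        else:
            self.concepts_ = None

        self.explicit_ = LayerTagger(
            layer="explicit", config=fcfg, c2=cfg.c2,
            max_iterations=cfg.max_iterations,
        ).fit(docs)

        hf_flags = None
        self._hf_cache: dict = {}
        if fcfg.hf:
            hf_flags = {
                doc.doc_id: hierarchical_feature(
                    self.explicit_,
                    doc,
                    doc.concept_spans,
                    fcfg.snapshot_encyclopedia,
                    _cache=self._hf_cache,
                )
                for doc in docs
            }
        self.implicit_ = LayerTagger(
            layer="implicit", config=fcfg, c2=cfg.c2,
            max_iterations=cfg.max_iterations,
        ).fit(docs, hf_flags=hf_flags)
        return self

    def predict(self, docs: list[Document]) -> list[PipelineResult]:
        if not hasattr(self, "explicit_"):
            raise RuntimeError("pipeline is not fitted")
        cfg = self._config()
        fcfg = cfg.features
        indicator = (
            gold_anatomy_indicator
            if cfg.cf_inference == "gold"
            else make_dict_indicator(fcfg.dict1)
            if fcfg.dict1 is not None
            else (lambda doc, m: False)
        )
        results = []
        for doc in docs:
            # Step 1: medical concepts
            if cfg.concept_source == "model":
                if self.concepts_ is None:
                    raise ValueError("concept_source='model' but no concepts model trained")
                concepts = self.concepts_.predict_document(doc)
            else:
                concepts = list(doc.concept_spans)

            # Step 2: explicit anatomical entities
            explicit = self.explicit_.predict_document(
                doc, concept_spans=concepts, coref_indicator=indicator
            )

            # Step 3: implicit anatomical entities (with HF)
            hf = None
            if fcfg.hf:
                hf = hierarchical_feature(
                    self.explicit_, doc, concepts, fcfg.snapshot_encyclopedia,
                    _cache=getattr(self, "_hf_cache", None),
                )
            implicit = self.implicit_.predict_document(
                doc, concept_spans=concepts, hf_flags=hf, coref_indicator=indicator
            )
            implicit = [replace(sp, label="implicit") for sp in implicit]
            explicit = [replace(sp, label="explicit") for sp in explicit]

            if cfg.overlap_policy == "explicit":
                implicit = _drop_overlaps(implicit, explicit, doc.doc_id)
            results.append(
                PipelineResult(
                    doc_id=doc.doc_id,
                    concept_spans=concepts,
                    explicit_spans=explicit,
                    implicit_spans=implicit,
                )
            )
        return results


def _drop_overlaps(
    implicit: list[EntitySpan], explicit: list[EntitySpan], doc_id: str
) -> list[EntitySpan]:
    kept = []
    for sp in implicit:
        clash = any(
            e.sentence_index == sp.sentence_index
            and sp.start < e.end
            and e.start < sp.end
            for e in explicit
        )
        if clash:
            logger.debug("%s: implicit span %s dropped (overlaps explicit)", doc_id, sp)
        else:
            kept.append(sp)
    return kept


# ---------------------------------------------------------------------------
# Thin functional wrappers and cross-validation


def train(docs: list[Document], layer: str, config: PipelineConfig) -> LayerTagger:
    fcfg = config.features
    tagger = LayerTagger(
        layer=layer, config=fcfg, c2=config.c2, max_iterations=config.max_iterations
    )
    hf_flags = None
    if layer == "implicit" and fcfg.hf:
        explicit = LayerTagger(
            layer="explicit", config=fcfg, c2=config.c2,
            max_iterations=config.max_iterations,
        ).fit(docs)
        cache: dict = {}
        hf_flags = {
            doc.doc_id: hierarchical_feature(
                explicit, doc, doc.concept_spans, fcfg.snapshot_encyclopedia, _cache=cache
            )
            for doc in docs
        }
    return tagger.fit(docs, hf_flags=hf_flags)


def run_pipeline(
    docs: list[Document], pipeline: AnatomyPipeline
) -> list[PipelineResult]:
    return pipeline.predict(docs)


def make_folds(n_docs: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded document-level partition into k folds of near-equal size."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_docs:
        raise ValueError(f"k={k} exceeds corpus size {n_docs}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_docs)
    return [order[i::k] for i in range(k)]


def crossval(
    docs: list[Document], k: int, config: PipelineConfig, seed: int | None = None
) -> dict:
    """k-fold cross-validation of the full pipeline.

    Each fold's models (including the explicit model behind HF) are
    trained only on that fold's training documents.  Returns the fitted
    per-fold pipelines and pooled predictions covering every document
    exactly once, in corpus order.
    """
    if seed is None:
        seed = config.seed
    folds = make_folds(len(docs), k, seed)
    predictions: dict[int, PipelineResult] = {}
    pipelines = []
    for test_idx in folds:
        test_set = set(int(i) for i in test_idx)
        train_docs = [d for i, d in enumerate(docs) if i not in test_set]
        test_docs = [docs[int(i)] for i in test_idx]
        pipe = AnatomyPipeline(config=config).fit(train_docs)
        pipelines.append(pipe)
        for i, res in zip(test_idx, pipe.predict(test_docs)):
            predictions[int(i)] = res
    pooled = [predictions[i] for i in range(len(docs))]
    return {"folds": folds, "pipelines": pipelines, "predictions": pooled}
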