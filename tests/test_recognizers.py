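import numpy as np
import pytest

from anatomyner.corpus_io import Document, EntitySpan
from anatomyner.crf import ChainCRF
from anatomyner.knowledge import KnowledgeSnapshot
from anatomyner.recognizers import (
    AnatomyPipeline,
    LayerTagger,
    PipelineConfig,
    crossval,
    hierarchical_feature,
    make_folds,
)
from anatomyner.synthetic import bundle_feature_config


@pytest.fixture(scope="module")
def fitted(small_separable_bundle):
    """One fitted pipeline (HF on) shared by the read-only tests."""
    bundle = small_separable_bundle
    cfg = PipelineConfig(features=bundle_feature_config(bundle, hf=True))
    pipe = AnatomyPipeline(config=cfg).fit(bundle.documents[:32])
    return bundle, pipe


class TestLayerTagger:
    def test_all_o_corpus_predicts_all_o(self, tiny_bundle):
        docs = []
        for doc in tiny_bundle.documents[:6]:
            bare = Document(doc_id=doc.doc_id, sentences=doc.sentences)
            docs.append(bare)
        cfg = bundle_feature_config(tiny_bundle, cf=False, wf1=False, wf2=False, wf3=False)
        with pytest.warns(UserWarning):
            tagger = LayerTagger(layer="explicit", config=cfg).fit(docs)
        assert all(not tagger.predict_document(d) for d in docs)

    def test_invalid_layer(self, tiny_bundle):
        with pytest.raises(ValueError, match="layer"):
            LayerTagger(layer="bogus").fit(tiny_bundle.documents[:2])

    def test_concepts_layer_multiclass(self, small_separable_bundle):
        bundle = small_separable_bundle
        cfg = bundle_feature_config(bundle)
        tagger = LayerTagger(layer="concepts", config=cfg, max_iterations=60).fit(
            bundle.documents[:24]
        )
        labels = {sp.label for d in bundle.documents[24:30] for sp in tagger.predict_document(d)}
        assert labels <= {"disease", "test", "treatment"}
        assert len(labels) >= 2


class TestHierarchicalFeature:
    def _explicit_tagger(self, bundle, docs):
        cfg = bundle_feature_config(bundle)
        return LayerTagger(layer="explicit", config=cfg).fit(docs)

    def test_linked_concept_flagged(self, fitted):
        """A concept whose definition names a recognizable anatomy term
        gets HF = 1 on all its tokens."""
        bundle, pipe = fitted
        doc = Document(
            doc_id="probe",
            sentences=[["history", "of", "hypertension", "noted", "."]],
            concept_spans=[EntitySpan(0, 2, 3, "disease")],
        )
        flags = hierarchical_feature(
            pipe.explicit_, doc, doc.concept_spans, bundle.snapshot_encyclopedia
        )
        assert flags == [[0, 0, 1, 0, 0]]

    def test_missing_snapshot_entry_zero(self, fitted):
        bundle, pipe = fitted
        doc = Document(
            doc_id="probe",
            sentences=[["unknownitis", "noted"]],
            concept_spans=[EntitySpan(0, 0, 1, "disease")],
        )
        flags = hierarchical_feature(
            pipe.explicit_, doc, doc.concept_spans, bundle.snapshot_encyclopedia
        )
        assert flags == [[0, 0]]

    def test_all_o_explicit_model_gives_zero(self, fitted, tiny_bundle):
        bundle, pipe = fitted
        bare = [
            Document(doc_id=d.doc_id, sentences=d.sentences)
            for d in bundle.documents[:6]
        ]
        with pytest.warns(UserWarning):
            null_tagger = self._explicit_tagger(bundle, bare)
        doc = Document(
            doc_id="probe",
            sentences=[["hypertension", "noted"]],
            concept_spans=[EntitySpan(0, 0, 1, "disease")],
        )
        flags = hierarchical_feature(
            null_tagger, doc, doc.concept_spans, bundle.snapshot_encyclopedia
        )
        assert flags == [[0, 0]]


class TestPipeline:
    def test_baseline_only_runs(self, small_separable_bundle):
        bundle = small_separable_bundle
        cfg = PipelineConfig(
            features=bundle_feature_config(
                bundle, df1=False, df2=False, cf=False,
                wf1=False, wf2=False, wf3=False, hf=False,
            )
        )
        pipe = AnatomyPipeline(config=cfg).fit(bundle.documents[:10])
        results = pipe.predict(bundle.documents[10:12])
        assert len(results) == 2

    def test_hf_isolation(self, small_separable_bundle):
        """Disabling HF changes only implicit predictions, never explicit."""
        bundle = small_separable_bundle
        train, test = bundle.documents[:32], bundle.documents[32:]
        with_hf = AnatomyPipeline(
            config=PipelineConfig(features=bundle_feature_config(bundle, hf=True))
        ).fit(train)
        without_hf = AnatomyPipeline(
            config=PipelineConfig(features=bundle_feature_config(bundle, hf=False))
        ).fit(train)
        for a, b in zip(with_hf.predict(test), without_hf.predict(test)):
            assert [s.key for s in a.explicit_spans] == [s.key for s in b.explicit_spans]

    def test_gold_vs_model_concepts_differ_only_in_step1(self, small_separable_bundle):
        bundle = small_separable_bundle
        train, test = bundle.documents[:32], bundle.documents[32:36]
        gold_cfg = PipelineConfig(
            features=bundle_feature_config(bundle, hf=True), concept_source="gold"
        )
        model_cfg = PipelineConfig(
            features=bundle_feature_config(bundle, hf=True), concept_source="model"
        )
        gold_pipe = AnatomyPipeline(config=gold_cfg).fit(train)
        model_pipe = AnatomyPipeline(config=model_cfg).fit(train)
        gold_res = gold_pipe.predict(test)
        model_res = model_pipe.predict(test)
        # Step 1 sources differ
        assert any(
            [s.key for s in g.concept_spans] != [s.key for s in m.concept_spans]
            or g.concept_spans == m.concept_spans
            for g, m in zip(gold_res, model_res)
        )
        # identical Step-1 output implies identical downstream predictions
        for g, m, doc in zip(gold_res, model_res, test):
            if sorted(s.key for s in g.concept_spans) == sorted(
                s.key for s in m.concept_spans
            ):
                assert sorted(s.key for s in g.implicit_spans) == sorted(
                    s.key for s in m.implicit_spans
                )

    def test_overlap_resolution_explicit_wins(self, fitted):
        bundle, pipe = fitted
        for res in pipe.predict(bundle.documents[32:]):
            for imp in res.implicit_spans:
                for exp in res.explicit_spans:
                    assert not (
                        imp.sentence_index == exp.sentence_index
                        and imp.start < exp.end
                        and exp.start < imp.end
                    )

    def test_missing_resources_config_error(self, tiny_bundle):
        cfg = PipelineConfig()  # features on, resources absent
        with pytest.raises(ValueError, match="missing resources"):
            AnatomyPipeline(config=cfg).fit(tiny_bundle.documents[:2])


class TestCrossval:
    def test_fold_sizes_and_coverage(self):
        folds = make_folds(11, 3, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert max(sizes) - min(sizes) <= 1
        assert sorted(int(i) for f in folds for i in f) == list(range(11))

    def test_leave_one_out(self):
        folds = make_folds(4, 4, seed=1)
        assert all(len(f) == 1 for f in folds)

    def test_same_seed_same_folds(self):
        a = make_folds(20, 5, seed=7)
        b = make_folds(20, 5, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_exceeds_docs(self):
        with pytest.raises(ValueError):
            make_folds(3, 5, seed=0)

    def test_pooled_predictions_cover_each_doc_once(self, small_separable_bundle):
        bundle = small_separable_bundle
        docs = bundle.documents[:12]
        cfg = PipelineConfig(
            features=bundle_feature_config(bundle, wf1=False, wf3=False, hf=False),
            max_iterations=40,
        )
        cv = crossval(docs, k=3, config=cfg, seed=0)
        assert [r.doc_id for r in cv["predictions"]] == [d.doc_id for d in docs]

    def test_no_test_fold_leakage(self, small_separable_bundle):
        """Removing a test-fold document leaves that fold's model
        parameters bit-identical."""
        bundle = small_separable_bundle
        docs = bundle.documents[:10]
        folds = make_folds(len(docs), 2, seed=0)
        test_set = {int(i) for i in folds[0]}
        train_docs = [d for i, d in enumerate(docs) if i not in test_set]
        cfg = PipelineConfig(
            features=bundle_feature_config(bundle, wf1=False, wf3=False, hf=False),
            max_iterations=40,
        )
        pipe_a = AnatomyPipeline(config=cfg).fit(train_docs)
        # drop one test-fold document from the corpus; training set unchanged
        dropped = sorted(test_set)[0]
        pruned = [d for i, d in enumerate(docs) if i != dropped and i not in test_set]
        assert [d.doc_id for d in pruned] == [d.doc_id for d in train_docs]
        pipe_b = AnatomyPipeline(config=cfg).fit(pruned)
        assert np.array_equal(pipe_a.explicit_.crf_.coef_emit_, pipe_b.explicit_.crf_.coef_emit_)
        assert np.array_equal(pipe_a.implicit_.crf_.coef_emit_, pipe_b.implicit_.crf_.coef_emit_)
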