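import numpy as np
import pytest

from anatomyner.corpus_io import EntitySpan, tokenize
from anatomyner.knowledge import (
    KnowledgeSnapshot,
    compute_wf1,
    compute_wf2,
    compute_wf3,
    definition_mentions_anatomy,
    load_stopwords,
)
from anatomyner.lexicon import compile_lexicon, normalize_term


@pytest.fixture()
def dict1():
    return compile_lexicon({"A": ["arteries", "heart", "lung", "spinal cord"]})


@pytest.fixture()
def snapshot_e(dict1):
    snap = KnowledgeSnapshot(kind="encyclopedia")
    snap.add(
        "hypertension",
        "High blood pressure is a chronic condition. It affects the arteries. "
        "It is common. The pancreas is not mentioned early.",
    )
    snap.add(
        "ecg",
        "An ECG records electrical activity. The heart generates the signal. "
        "Leads are attached to the skin.",
    )
    snap.add(
        "late",
        "Sentence one here. Sentence two here. Sentence three here. "
        "The lung appears only now.",
    )
    snap.add("plain", "Nothing anatomical at all. Really nothing. None.")
    return snap


class TestEffectiveDefinition:
    def test_absent_term(self, snapshot_e):
        assert snapshot_e.effective_definition(("missing",)) is None

    def test_encyclopedia_truncates_to_three_sentences(self, snapshot_e):
        defn = snapshot_e.effective_definition(("hypertension",))
        assert "arteries" in defn
        assert "pancreas" not in defn  # 4th sentence cut

    def test_lexical_keeps_full_text(self):
        snap = KnowledgeSnapshot(kind="lexical")
        text = "One. Two. Three. Four has the lung. Five."
        snap.add("term", text)
        assert snap.effective_definition(("term",)) == text

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            KnowledgeSnapshot(kind="wiki")

    def test_save_load_roundtrip(self, tmp_path, snapshot_e):
        path = tmp_path / "snap.jsonl"
        snapshot_e.save(path)
        loaded = KnowledgeSnapshot.load(path)
        assert loaded.kind == "encyclopedia"
        assert loaded.entries == snapshot_e.entries


class TestDefinitionMentionsAnatomy:
    def test_positive(self, dict1):
        assert definition_mentions_anatomy(
            "High blood pressure affecting the arteries .", dict1
        )

    def test_negative(self, dict1):
        assert not definition_mentions_anatomy("Nothing relevant here .", dict1)

    def test_multiword_entry(self, dict1):
        assert definition_mentions_anatomy("Injury of the spinal cord.", dict1)

    def test_agrees_with_ngram_oracle(self, dict1):
        rng = np.random.default_rng(6)
        vocab = ["arteries", "the", "lung", "spinal", "cord", "pressure", "none."]
        for _ in range(200):
            words = [vocab[int(i)] for i in rng.integers(0, len(vocab), rng.integers(1, 10))]
            text = " ".join(words)
            tokens = tokenize(text)
            norm = [normalize_term(t) for t in tokens]
            oracle = any(
                all(norm[i:j])
                and tuple(t for sub in norm[i:j] for t in sub) in dict1.entries
                for i in range(len(tokens))
                for j in range(i + 1, len(tokens) + 1)
            )
            assert definition_mentions_anatomy(text, dict1) == oracle


class TestWF1:
    def test_all_stopwords(self, snapshot_e, dict1):
        stop = load_stopwords()
        assert compute_wf1(["the", "and", "in"], stop, snapshot_e, dict1) == [0, 0, 0]

    def test_ecg_flagged(self, snapshot_e, dict1):
        stop = load_stopwords()
        flags = compute_wf1(["ecg", "was", "normal"], stop, snapshot_e, dict1)
        assert flags == [1, 0, 0]

    def test_plain_entry_not_flagged(self, snapshot_e, dict1):
        stop = load_stopwords()
        assert compute_wf1(["plain"], stop, snapshot_e, dict1) == [0]

    def test_matches_per_token_brute_force(self, snapshot_e, dict1):
        stop = load_stopwords()
        rng = np.random.default_rng(7)
        vocab = ["ecg", "hypertension", "late", "plain", "the", "normal", "exam"]
        for _ in range(300):
            sent = [vocab[int(i)] for i in rng.integers(0, len(vocab), rng.integers(1, 8))]
            got = compute_wf1(sent, stop, snapshot_e, dict1)
            oracle = []
            for tok in sent:
                if tok.lower() in stop:
                    oracle.append(0)
                    continue
                defn = snapshot_e.effective_definition(normalize_term(tok))
                oracle.append(
                    int(defn is not None and definition_mentions_anatomy(defn, dict1))
                )
            assert got == oracle


class TestWF2WF3:
    def test_no_concept_spans(self, snapshot_e, dict1):
        flags = compute_wf2([], [["a", "b"]], snapshot_e, dict1)
        assert flags == [[0, 0]]

    def test_all_words_of_span_set(self, dict1):
        snap = KnowledgeSnapshot(kind="encyclopedia")
        snap.add(
            "coronary angiography",
            "A test imaging the heart. It uses contrast dye. It is invasive.",
        )
        sentences = [["coronary", "angiography", "was", "done"]]
        spans = [EntitySpan(0, 0, 2, "test")]
        assert compute_wf2(spans, sentences, snap, dict1) == [[1, 1, 0, 0]]

    def test_absent_concept_zero(self, snapshot_e, dict1):
        sentences = [["unknownitis", "found"]]
        spans = [EntitySpan(0, 0, 1, "disease")]
        assert compute_wf2(spans, sentences, snapshot_e, dict1) == [[0, 0]]

    def test_truncation_hides_late_mention(self, snapshot_e, dict1):
        sentences = [["late"]]
        spans = [EntitySpan(0, 0, 1, "disease")]
        # encyclopedia: anatomy appears only in sentence 4 -> truncated away
        assert compute_wf2(spans, sentences, snapshot_e, dict1) == [[0]]
        # lexical: full text counts
        snap_l = KnowledgeSnapshot(kind="lexical")
        snap_l.entries = dict(snapshot_e.entries)
        assert compute_wf3(spans, sentences, snap_l, dict1) == [[1]]

    def test_kind_enforced(self, snapshot_e, dict1):
        with pytest.raises(ValueError):
            compute_wf3([], [[]], snapshot_e, dict1)

    def test_wf2_wf3_independent(self, dict1):
        snap_e = KnowledgeSnapshot(kind="encyclopedia")
        snap_l = KnowledgeSnapshot(kind="lexical")
        snap_e.add("pneumonia", "An infection. It involves the lung. Often febrile.")
        snap_l.add("pneumonia", "Inflammation of the lung.")
        sentences = [["pneumonia"]]
        spans = [EntitySpan(0, 0, 1, "disease")]
        assert compute_wf2(spans, sentences, snap_e, dict1) == [[1]]
        assert compute_wf3(spans, sentences, snap_l, dict1) == [[1]]


class TestInvariants:
    def test_removing_entry_monotone(self, snapshot_e, dict1):
        """Deleting a snapshot entry can only flip flags 1 -> 0."""
        stop = load_stopwords()
        sent = ["ecg", "hypertension", "plain"]
        before = compute_wf1(sent, stop, snapshot_e, dict1)
        reduced = KnowledgeSnapshot(kind="encyclopedia")
        reduced.entries = {
            k: v for k, v in snapshot_e.entries.items() if k != ("ecg",)
        }
        after = compute_wf1(sent, stop, reduced, dict1)
        assert all(a <= b for a, b in zip(after, before))

    def test_appending_after_third_sentence_is_inert(self, dict1):
        stop = load_stopwords()
        base = "An entry. It involves the heart. Third sentence."
        snap_a = KnowledgeSnapshot(kind="encyclopedia")
        snap_a.add("term", base)
        snap_b = KnowledgeSnapshot(kind="encyclopedia")
        snap_b.add("term", base + " Extra about the lung. More extra.")
        sent = ["term"]
        assert compute_wf1(sent, stop, snap_a, dict1) == compute_wf1(
            sent, stop, snap_b, dict1
        )

    def test_flags_ignore_other_tokens(self, snapshot_e, dict1):
        stop = load_stopwords()
        a = compute_wf1(["ecg", "alpha"], stop, snapshot_e, dict1)
        b = compute_wf1(["ecg", "beta"], stop, snapshot_e, dict1)
        assert a[0] == b[0] == 1
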