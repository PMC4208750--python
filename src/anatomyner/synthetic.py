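"""Seeded synthetic corpora emulating discharge-summary structure.

The restricted clinical corpus cannot be redistributed, so every stage
of the framework is exercised on generated documents instead.  The
generator writes template-based sentences with exact gold labels:

* explicit anatomy mentions, optionally preceded by a positional
  modifier ("bilateral knees") — the gold span then covers both tokens;
* medical-concept mentions (disease / test / treatment) that are either
  true implicit anatomical entities — their knowledge-base definition
  mentions the associated anatomy term with probability ``p_link`` — or
  distractors of identical surface shape whose definitions mention
  anatomy only with probability ``p_distractor_link``;
* positional-adjective implicit entities ("supraclavicular"-style) that
  have no concept span at all;
* local abbreviations tied to their full form by a coreference chain;
* ambiguous uses of entity words ("back" as a body part vs adverb,
  "left" as a laterality vs verb) in distinct, learnable frames.

Vocabularies are pseudo-words built from syllables with class-flavored
suffixes, so implicit terms and distractors are not separable by
morphology — only knowledge features (or memorization) can tell them
apart.  The same seed always yields a byte-identical bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .corpus_io import CorefChain, Document, EntitySpan, Mention
from .knowledge import KnowledgeSnapshot
from .lexicon import Lexicon, compile_lexicon, normalize_term

CONCEPT_CLASSES = ("disease", "test", "treatment")

# real seed terms keep worked examples readable; pseudo-words fill the pools
_CORE_ANATOMY = [
    "lung", "heart", "liver", "kidney", "spleen", "femur", "tibia", "aorta",
    "trachea", "colon", "breast", "brain", "arteries", "back", "chest",
    "abdomen", "pelvis", "spine", "left ventricle", "spinal cord",
    "chest wall", "frontal lobe", "carotid artery", "optic nerve",
]
_CORE_IMPLICIT = {
    "disease": [("pneumonia", "lung"), ("hypertension", "arteries")],
    "test": [("ecg", "heart"), ("colonoscopy", "colon")],
    "treatment": [("mastectomy", "breast"), ("angioplasty", "arteries")],
}

_SYLLABLES = [
    "bra", "cho", "den", "fir", "gal", "hem", "jun", "kel", "lor", "mun",
    "nar", "pol", "qua", "ril", "sor", "tam", "uln", "vex", "wil", "zon",
]
_CLASS_SUFFIX = {
    "disease": ["itis", "osis", "oma"],
    "test": ["gram", "scopy", "assay"],
    "treatment": ["ectomy", "plasty", "apexy"],
}

_MODIFIERS = ["left", "right", "bilateral", "distal", "proximal", "upper", "lower"]

_EXPLICIT_FRAMES = [
    ("examination of the", "was unremarkable ."),
    ("patient reports pain in the", "today ."),
    ("imaging showed a lesion in the", "."),
    ("palpation of the", "elicited tenderness ."),
]
_CONCEPT_FRAMES = {
    "disease": [
        ("history of", "was noted ."),
        ("the patient was diagnosed with", "."),
    ],
    "test": [
        ("", "was performed on admission ."),
        ("results of the", "were reviewed ."),
    ],
    "treatment": [
        ("the patient underwent", "last year ."),
        ("", "was scheduled for next week ."),
    ],
}
_FILLER_SENTENCES = [
    "the patient was resting comfortably .",
    "vital signs were stable overnight .",
    "he was discharged home in good condition .",
    "follow up was arranged with the provider .",
    "medications were continued without change .",
    "the family was updated at the bedside .",
]
_AMBIG_ENTITY = "pain in the lower back persisted ."  # gold: "lower back"
_AMBIG_NONENTITY = [
    "the patient came back to the clinic .",
    "the patient left the hospital against advice .",
]
_POSITIONAL_PREFIXES = ["supra", "infra", "peri"]
_POSITIONAL_STEMS = ["clavicular", "orbital", "umbilical", "scapular"]
# body area each positional adjective points at (for the association map)
_POSITIONAL_ANATOMY = {
    "clavicular": "chest wall",
    "orbital": "brain",
    "umbilical": "abdomen",
    "scapular": "back",
}


@dataclass
class GeneratorSpec:
    """The stated world of the synthetic corpus.

    Defaults emulate a mid-sized annotated discharge-summary set: 200
    documents of 8–15 sentences; concept vocabularies large enough that
    held-out folds contain terms unseen in training (so knowledge
    features carry real information); a 0.9 probability that a true
    implicit term's definition names its anatomy within the first three
    sentences and a 0.05 probability that a distractor's does.
    """

    seed: int = 0
    n_docs: int = 200
    sentences_per_doc: tuple[int, int] = (8, 15)
    n_anatomy_terms: int = 60
    n_implicit_per_class: int = 80
    n_distractor_per_class: int = 80
    p_link: float = 0.9
    p_distractor_link: float = 0.05
    p_modifier: float = 0.3
    p_abbrev: float = 0.15
    ambiguity_rate: float = 0.08
    positional_rate: float = 0.04
    snapshot_coverage: float = 1.0
    dictionary_degradation: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_link", "p_distractor_link", "p_modifier", "p_abbrev",
            "ambiguity_rate", "positional_rate", "snapshot_coverage",
            "dictionary_degradation",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_anatomy_terms < 1 or self.n_implicit_per_class < 1:
            raise ValueError("vocabularies must be non-empty")

    @classmethod
    def separable(cls, seed: int = 0, **overrides) -> "GeneratorSpec":
        """The fully separable world: every implicit term's definition
        links to anatomy, no distractor's does, full dictionary and
        snapshots."""
        return cls(
            seed=seed,
            p_link=1.0,
            p_distractor_link=0.0,
            snapshot_coverage=1.0,
            dictionary_degradation=0.0,
            **overrides,
        )


@dataclass
class SyntheticBundle:
    spec: GeneratorSpec
    documents: list[Document]
    dict1: Lexicon
    dict2: Lexicon
    snapshot_encyclopedia: KnowledgeSnapshot
    snapshot_lexical: KnowledgeSnapshot
    association: dict[str, str] = field(default_factory=dict)  # implicit term -> anatomy


def _pseudo_words(rng: np.random.Generator, n: int, suffixes: list[str], taken: set[str]) -> list[str]:
    words = []
    while len(words) < n:
        k = int(rng.integers(2, 4))
        stem = "".join(rng.choice(_SYLLABLES) for _ in range(k))
        word = stem + suffixes[int(rng.integers(len(suffixes)))]
        if word not in taken:
            taken.add(word)
            words.append(word)
    return words


def _build_vocab(spec: GeneratorSpec, rng: np.random.Generator):
    taken: set[str] = set(_CORE_ANATOMY)
    anatomy = list(_CORE_ANATOMY)
    if spec.n_anatomy_terms > len(anatomy):
        anatomy += _pseudo_words(
            rng, spec.n_anatomy_terms - len(anatomy), ["ium", "eon", "ax"], taken
        )
    anatomy = anatomy[: spec.n_anatomy_terms]

    implicit: dict[str, list[str]] = {}
    distractor: dict[str, list[str]] = {}
    association: dict[str, str] = {}
    for cls in CONCEPT_CLASSES:
        core = [t for t, _ in _CORE_IMPLICIT[cls]]
        terms = list(core)
        if spec.n_implicit_per_class > len(terms):
            terms += _pseudo_words(
                rng, spec.n_implicit_per_class - len(terms), _CLASS_SUFFIX[cls], taken
            )
        terms = terms[: spec.n_implicit_per_class]
        for term in terms:
            fixed = dict(_CORE_IMPLICIT[cls]).get(term)
            association[term] = fixed or anatomy[int(rng.integers(len(anatomy)))]
        implicit[cls] = terms
        distractor[cls] = _pseudo_words(
            rng, spec.n_distractor_per_class, _CLASS_SUFFIX[cls], taken
        )
    return anatomy, implicit, distractor, association


def _definition_sentences(
    term: str, cls: str, anatomy: str | None, link: str, rng: np.random.Generator
) -> list[str]:
    """Definition text; ``link`` is 'early' (sentence 1–3), 'late'
    (after sentence 3, exercising encyclopedia truncation) or 'none'."""
    kind_word = {"disease": "disorder", "test": "procedure", "treatment": "intervention"}[cls]
    filler = [
        f"{term.capitalize()} is a {kind_word} described in clinical practice.",
        "It is encountered in patients of all ages.",
        "Severity varies between individuals.",
        "Documentation in the record is recommended.",
        "Outcomes depend on timely management.",
    ]
    if anatomy is None or link == "none":
        return filler[:4]
    # phrased in the same register as the corpus so the explicit
    # recognizer can generalize to definition text (as it must for HF)
    anat_sentence = f"Imaging often shows a lesion in the {anatomy}."
    if link == "early":
        pos = int(rng.integers(0, 3))
        out = filler[:3]
        out.insert(pos, anat_sentence)
        return out[:3] + filler[3:4]
    # late: anatomy only after the third sentence
    return filler[:3] + [anat_sentence, filler[4]]


def _lexical_gloss(term: str, cls: str, anatomy: str | None, linked: bool) -> str:
    """Short full-text gloss; when linked, the anatomy term is always
    present (lexical definitions are never truncated)."""
    kind_word = {"disease": "disorder", "test": "procedure", "treatment": "intervention"}[cls]
    first = f"{term.capitalize()} is a {kind_word} described in clinical practice."
    if linked and anatomy is not None:
        return first + f" It chiefly involves the {anatomy} of the patient."
    return first + " Severity varies between individuals."


def _abbreviate(term: str) -> str:
    parts = term.split()
    if len(parts) > 1:
        return "".join(p[0] for p in parts)
    return term[:3]


def _make_document(
    doc_index: int,
    spec: GeneratorSpec,
    rng: np.random.Generator,
    anatomy: list[str],
    implicit: dict[str, list[str]],
    distractor: dict[str, list[str]],
) -> Document:
    n_sent = int(rng.integers(spec.sentences_per_doc[0], spec.sentences_per_doc[1] + 1))
    doc = Document(doc_id=f"synth-{doc_index:04d}", sentences=[])
    abbrev_budget = 2
    pending_abbrev: list[tuple[str, Mention]] = []  # (abbrev token, full-form mention)

    for s in range(n_sent):
        roll = rng.random()
        if roll < 0.30:
            _explicit_sentence(doc, s, spec, rng, anatomy, pending_abbrev, abbrev_budget)
        elif roll < 0.64:
            _concept_sentence(doc, s, rng, implicit, distractor)
        elif roll < 0.64 + spec.ambiguity_rate:
            _ambiguous_sentence(doc, s, rng)
        elif roll < 0.64 + spec.ambiguity_rate + spec.positional_rate:
            _positional_sentence(doc, s, rng)
        elif pending_abbrev:
            token, full_mention = pending_abbrev.pop(0)
            words = [token, "was", "stable", "."]
            doc.sentences.append(words)
            doc.anatomy_spans.append(EntitySpan(s, 0, 1, "explicit"))
            doc.chains.append(
                CorefChain(
                    chain_id=f"{doc.doc_id}-ch{len(doc.chains)}",
                    mentions=(full_mention, Mention(s, 0, 1)),
                )
            )
        else:
            filler = _FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))]
            doc.sentences.append(filler.split())
    doc.validate()
    return doc


def _explicit_sentence(doc, s, spec, rng, anatomy, pending_abbrev, abbrev_budget):
    term = anatomy[int(rng.integers(len(anatomy)))]
    words_term = term.split()
    use_modifier = rng.random() < spec.p_modifier
    if use_modifier:
        mod = _MODIFIERS[int(rng.integers(len(_MODIFIERS)))]
        words_term = [mod] + words_term
    head, tail = _EXPLICIT_FRAMES[int(rng.integers(len(_EXPLICIT_FRAMES)))]
    words = head.split() + words_term + tail.split()
    start = len(head.split())
    end = start + len(words_term)
    doc.sentences.append(words)
    doc.anatomy_spans.append(EntitySpan(s, start, end, "explicit"))
    if (
        len(doc.chains) + len(pending_abbrev) < abbrev_budget
        and len(term) >= 4
        and rng.random() < spec.p_abbrev
    ):
        pending_abbrev.append((_abbreviate(term), Mention(s, start, end)))


def _concept_sentence(doc, s, rng, implicit, distractor):
    cls = CONCEPT_CLASSES[int(rng.integers(len(CONCEPT_CLASSES)))]
    is_implicit = rng.random() < 0.5
    pool = implicit[cls] if is_implicit else distractor[cls]
    term = pool[int(rng.integers(len(pool)))]
    head, tail = _CONCEPT_FRAMES[cls][int(rng.integers(len(_CONCEPT_FRAMES[cls])))]
    words = head.split() + term.split() + tail.split()
    start = len(head.split())
    end = start + len(term.split())
    doc.sentences.append(words)
    doc.concept_spans.append(EntitySpan(s, start, end, cls))
    if is_implicit:
        doc.anatomy_spans.append(EntitySpan(s, start, end, "implicit"))


def _ambiguous_sentence(doc, s, rng):
    if rng.random() < 0.5:
        words = _AMBIG_ENTITY.split()
        doc.sentences.append(words)
        i = words.index("lower")
        doc.anatomy_spans.append(EntitySpan(s, i, i + 2, "explicit"))
    else:
        choice = _AMBIG_NONENTITY[int(rng.integers(len(_AMBIG_NONENTITY)))]
        doc.sentences.append(choice.split())


def _positional_sentence(doc, s, rng):
    prefix = _POSITIONAL_PREFIXES[int(rng.integers(len(_POSITIONAL_PREFIXES)))]
    stem = _POSITIONAL_STEMS[int(rng.integers(len(_POSITIONAL_STEMS)))]
    words = ["there", "was", prefix + stem, "tenderness", "."]
    doc.sentences.append(words)
    doc.anatomy_spans.append(EntitySpan(s, 2, 3, "implicit"))


def generate(spec: GeneratorSpec) -> SyntheticBundle:
    """Generate a fully labeled bundle; same spec -> identical output."""
    rng = np.random.default_rng(spec.seed)
    anatomy, implicit, distractor, association = _build_vocab(spec, rng)
    for prefix in _POSITIONAL_PREFIXES:
        for stem, anat in _POSITIONAL_ANATOMY.items():
            association[prefix + stem] = anat

    documents = [
        _make_document(i, spec, rng, anatomy, implicit, distractor)
        for i in range(spec.n_docs)
    ]

    dict1 = compile_lexicon({"synthetic_anatomy": anatomy}, name="Dictionary-1")
    if spec.dictionary_degradation > 0:
        dict1 = degrade_lexicon(dict1, spec.dictionary_degradation, spec.seed)
    dict2 = compile_lexicon({"synthetic_positions": _MODIFIERS}, name="Dictionary-2")

    snap_e = KnowledgeSnapshot(kind="encyclopedia")
    snap_l = KnowledgeSnapshot(kind="lexical")
    for cls in CONCEPT_CLASSES:
        for term in implicit[cls]:
            anat = association[term]
            if rng.random() >= spec.snapshot_coverage:
                continue
            if rng.random() < spec.p_link:
                link = "early"
            elif rng.random() < 0.5:
                link = "late"
            else:
                link = "none"
            snap_e.add(term, " ".join(_definition_sentences(term, cls, anat, link, rng)))
            snap_l.add(term, _lexical_gloss(term, cls, anat, rng.random() < spec.p_link))
        for term in distractor[cls]:
            if rng.random() >= spec.snapshot_coverage:
                continue
            link = "early" if rng.random() < spec.p_distractor_link else "none"
            snap_e.add(
                term,
                " ".join(_definition_sentences(term, cls, anatomy[0], link, rng)),
            )
            snap_l.add(
                term,
                _lexical_gloss(term, cls, anatomy[0], rng.random() < spec.p_distractor_link),
            )

    return SyntheticBundle(
        spec=spec,
        documents=documents,
        dict1=dict1,
        dict2=dict2,
        snapshot_encyclopedia=snap_e,
        snapshot_lexical=snap_l,
        association=dict(sorted(association.items())),
    )


def degrade_lexicon(dict1: Lexicon, rate: float, seed: int) -> Lexicon:
    """Withhold a seeded ceil(rate * |entries|) subset of entries,
    emulating the partial coverage of real resources."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    entries = sorted(dict1.entries)
    n_remove = math.ceil(rate * len(entries))
    rng = np.random.default_rng(seed)
    removed = set(
        tuple(entries[int(i)])
        for i in rng.choice(len(entries), size=n_remove, replace=False)
    )
    kept = Lexicon(name=dict1.name)
    for entry in entries:
        if entry not in removed:
            kept.entries.add(entry)
            kept.provenance[entry] = set(dict1.provenance.get(entry, set()))
    return kept


def bundle_feature_config(bundle: SyntheticBundle, **toggles):
    """A :class:`~anatomyner.features.FeatureConfig` wired to the
    bundle's lexicons and snapshots; keyword overrides set toggles."""
    from .features import FeatureConfig

    cfg = FeatureConfig(
        dict1=bundle.dict1,
        dict2=bundle.dict2,
        snapshot_encyclopedia=bundle.snapshot_encyclopedia,
        snapshot_lexical=bundle.snapshot_lexical,
    )
    return dc_replace(cfg, **toggles) if toggles else cfg
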