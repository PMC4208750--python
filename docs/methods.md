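# Methods

## Problem and model

Anatomical information in clinical narratives is carried both by
explicit location terms and by implicit references — diseases, clinical
tests and treatments tied to a specific body component. The package
treats recognition as three cooperating BIO sequence-labeling problems
over tokenized sentences:

- **concepts** (Step 1): multi-class tags `B-disease … I-treatment / O`
  over the medical-concept layer (or a gold-annotation passthrough);
- **explicit** (Step 2) and **implicit** (Step 3): binary `B/I/O` tags
  over the anatomy layer, one model per class.

Each labeler is a linear-chain conditional random field

$$p(y\mid x)=\frac{1}{Z(x)}\exp\Big(\sum_t w_e[f(x_t),y_t]
  +\sum_t w_T[y_{t-1},y_t]+w_s[y_1]+w_f[y_T]\Big)$$

with categorical indicator features, trained by maximizing the L2-
penalized conditional log-likelihood (penalty $c_2\lVert w\rVert^2$,
default $c_2=1$, at most 100 L-BFGS iterations, `ftol` $10^{-6}$) and
decoded with Viterbi. The forward–backward recursions run in log space,
batched over all sentences at once, so training is pure NumPy/SciPy and
deterministic given the input order and configuration. The engine is
implemented in-package (`anatomyner.crf`) because no linear-chain CRF
library is available in the target environment; it exposes the familiar
sklearn-style estimator surface (`fit`/`predict`, `get_params`,
fitted attributes with trailing underscores) and accepts the
conventional input shape — a list of sentences, each a list of
`{feature name: value}` dicts.

## Features

Per token (window-expanded to ±2 neighbors by default, with
`BOS`/`EOS` padding markers):

| group | features | notes |
|---|---|---|
| baseline | `Original`, `Norm` (lowercase, digit runs → `#`), `CapUpper`, `AllUpper`, `Prefix1..8`, `Suffix1..8`, `POS_A`/`POS_B`, `ConceptType` | affixes are the contiguous prefixes/suffixes of lengths 1–8; POS comes from up to two pluggable providers (a deterministic rule tagger ships as the default); `ConceptType` is the covering Step-1 span's class |
| gazetteer | `DF1`, `DF2` | 1 iff the token lies inside any n-gram matching the anatomy dictionary (DF1) or the positional-modifier list (DF2) |
| coreference | `CF` | 1 for every token of every mention in a chain containing at least one anatomical mention (gold membership at training; dictionary-match or gold, per config, at inference) |
| world knowledge | `WF1`, `WF2`, `WF3` | WF1: per non-stopword token, its encyclopedia definition mentions an anatomy-dictionary term; WF2/WF3: per Step-1 concept span, the span's encyclopedia (first three sentences) / lexical (full gloss) definition mentions anatomy — set on **all** tokens of the span |
| hierarchical | `HF` | implicit layer only: the trained explicit recognizer is applied to the concept's truncated encyclopedia definition; 1 for all concept tokens iff it predicts at least one explicit span |

Binary flags are emitted only when set. With explicit `flag=0`
features, the ubiquitous zero-variants act as class-prior features:
they dominate exactly where context is out-of-vocabulary — the
definition text that HF must generalize to — and suppress the gazetteer
signal there. Emitting only positives is the standard CRF-tagger
convention and keeps rare indicators informative.

Schema compatibility is therefore enforced from the feature
*configuration* (the set of enabled feature names plus window), not
from observed rows; a tagger refuses to predict under a configuration
whose schema hash differs from training.

## Pipeline and protocol

Training-time concept-dependent features (`ConceptType`, WF2, WF3, HF)
use gold concept spans; at inference they use gold or predicted
concepts (`concept_source`), mirroring the two experimental modes the
framework is meant for. HF definitions are featurized with the same
schema as the explicit model but with coreference and world-knowledge
resources emptied, i.e. baseline + DF1/DF2 only — a definition has no
chains or concept annotations of its own. Within cross-validation,
every model a fold uses — including the explicit model behind HF — is
trained on that fold's training documents only. Folds are a seeded
document-level partition with sizes differing by at most one.

Overlaps between predicted explicit and implicit spans are resolved in
favor of the explicit layer (the annotation scheme makes the classes
disjoint); dropped spans are logged. Predicted BIO sequences are
decoded leniently: a dangling `I` opens a new span, and `I`-after-`O`
on file input is repaired to `B` and logged — the usual CoNLL
convention.

Evaluation is strict span-level: a prediction counts only when both
token boundaries match a gold span. Micro scores pool TP/FP/FN across
the explicit and implicit classes before applying P/R/F. Token-level
counts are reported alongside, since corpus statistics and agreement
tables are naturally token-based; Cohen's kappa is computed over
token-level binary (entity vs O) decisions and is undefined when the
chance agreement is 1. All reported fractions are rounded half-even to
four decimals; coverage percentages to two.

## The synthetic world

The clinical corpus the framework targets cannot be redistributed, so
everything is exercised on a generated stand-in with exact gold labels
(`anatomyner.synthetic`). Defaults: 200 documents of 8–15 template
sentences; 60 anatomy terms (a real-term core plus syllable-generated
pseudo-words); 80 implicit and 80 distractor terms per concept class;
`p_link = 0.9` (a true implicit term's definition names its anatomy
within the first three sentences), `p_distractor_link = 0.05`,
`p_modifier = 0.3`, `p_abbrev = 0.15`, full snapshots, no dictionary
degradation. `GeneratorSpec.separable()` pins `p_link = 1`,
`p_distractor_link = 0` — the fully separable stated world used by the
acceptance checks. Concept vocabularies are deliberately larger than
the corpus can exhaust, so held-out folds contain terms never seen in
training: without knowledge features the implicit layer can only
memorize vocabulary, which is precisely the failure mode the WF/HF
features exist to fix, and the measured F1 drop when they are removed
is the designed-for effect, not an artifact. Implicit terms and
distractors share morphology (class-flavored suffixes) and sentence
frames, so surface features cannot separate them.

Two generator choices deserve note. First, definition texts place the
anatomy mention in a sentence phrased in the same register as the
corpus ("Imaging often shows a lesion in the …"): real encyclopedia
prose shares ordinary-language context with clinical text, which is
what lets a clinically-trained explicit recognizer find entities in
definitions at all; a register gap would make HF structurally dead
rather than hard. Second, ambiguity is injected with genuinely
learnable context ("pain in the lower back" vs "came back to the
clinic"), because feature efficacy cannot be demonstrated against
noise that nothing can resolve. Limitations: template sentences have
none of the lexical variety, misspellings, section structure or
de-identification artifacts of real discharge summaries, so a green
suite establishes correctness of the machinery and the direction of
feature effects — not clinical-grade accuracy figures.

## Numerical and design choices

- **Tokenization**: whitespace split, leading/trailing punctuation
  split off; sentence splitting on `.!?` + whitespace + capital/digit.
  Over-splitting at abbreviation periods is tolerated (knowledge flags
  are robust to it).
- **Dictionary matching**: case-insensitive over normalized tokens,
  all covering n-grams (not leftmost-longest) since the DF feature is
  per-token membership; punctuation-only tokens act as match
  boundaries so DF never marks punctuation; no stemming — morphology
  is the affix features' job. Knowledge-base lookup is exact on the
  normalized span text, no fuzzy fallback (WF1 is the designed
  mitigation for lookup misses).
- **Abbreviations**: the default pipeline uses the CF feature; an
  opt-in substitution mode rewrites abbreviation tokens to their
  chain's longest full form before tagging.
- **Offsets**: 0-based half-open token spans throughout.
- **Degenerate inputs**: single-class training warns (degenerate
  model); empty corpora and overlapping same-layer spans are errors;
  kappa on empty input is an error, on degenerate marginals `None`.
- **Scale-downs for test runtime**: unit and property tests use
  bundles of 10–40 documents with capped optimizer iterations; the
  learning-curve monotonicity property uses 5 seeds at sizes 6 vs 24
  with 2 folds. The acceptance suite runs the full 200-document world.
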