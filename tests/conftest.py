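import numpy as np
import pytest

from anatomyner.corpus_io import Document, EntitySpan
from anatomyner.synthetic import GeneratorSpec, generate


@pytest.fixture(scope="session")
def tiny_bundle():
    """16 small documents; enough structure for I/O and feature tests."""
    return generate(GeneratorSpec(seed=5, n_docs=16))


@pytest.fixture(scope="session")
def small_separable_bundle():
    """40 documents from the fully separable world (fast CRF training)."""
    return generate(GeneratorSpec.separable(seed=3, n_docs=40))


def random_spans(rng: np.random.Generator, length: int, label: str = "explicit"):
    """Random non-overlapping spans within one sentence."""
    spans = []
    pos = 0
    while pos < length:
        if rng.random() < 0.4:
            width = int(rng.integers(1, min(3, length - pos) + 1))
            spans.append(EntitySpan(0, pos, pos + width, label))
            pos += width
        pos += int(rng.integers(1, 3))
    return spans


def make_doc(sentences, anatomy=(), concepts=(), doc_id="d0"):
    return Document(
        doc_id=doc_id,
        sentences=[s.split() if isinstance(s, str) else list(s) for s in sentences],
        anatomy_spans=list(anatomy),
        concept_spans=list(concepts),
    )
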