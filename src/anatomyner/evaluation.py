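"""Strict-boundary evaluation, agreement, and experiment reports.

The primary metric is span-level strict matching: a predicted entity
counts as a true positive only when both its left and right token
boundaries equal a gold span's.  Precision, recall and F1 follow the
usual definitions; micro-averaged scores pool TP/FP/FN counts across the
explicit and implicit classes before applying the formulas.  Token-level
counts are also emitted because corpus statistics and inter-annotator
agreement are naturally token-based.

All reported fractions are rounded half-even to four decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Document, EntitySpan

ROUND = 4


def _validate_no_overlap(spans: list[EntitySpan]) -> None:
    ordered = sorted(spans, key=lambda s: (s.sentence_index, s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.sentence_index == b.sentence_index and b.start < a.end:
            raise ValueError(f"overlapping spans {a} / {b}")


def strict_match(
    gold: list[EntitySpan], pred: list[EntitySpan]
) -> tuple[int, int, int]:
    """Span-level TP/FP/FN under exact (sentence, start, end) equality."""
    _validate_no_overlap(gold)
    _validate_no_overlap(pred)
    gold_keys = {sp.key for sp in gold}
    pred_keys = {sp.key for sp in pred}
    tp = len(gold_keys & pred_keys)
    return tp, len(pred_keys) - tp, len(gold_keys) - tp


def token_match(
    gold: list[EntitySpan], pred: list[EntitySpan]
) -> tuple[int, int, int]:
    """Token-level TP/FP/FN: per-token membership in any span."""
    gold_tokens = {
        (sp.sentence_index, i) for sp in gold for i in range(sp.start, sp.end)
    }
    pred_tokens = {
        (sp.sentence_index, i) for sp in pred for i in range(sp.start, sp.end)
    }
    tp = len(gold_tokens & pred_tokens)
    return tp, len(pred_tokens) - tp, len(gold_tokens) - tp


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    return p, r


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall, rounded half-even to 4 dp."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError(f"precision/recall must be in [0, 1], got {p}, {r}")
    if p + r == 0.0:
        return 0.0
    return round(2.0 * p * r / (p + r), ROUND)


def prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    p, r = precision_recall(tp, fp, fn)
    return {"P": round(p, ROUND), "R": round(r, ROUND), "F": f1(p, r)}


def micro(counts: dict[str, tuple[int, int, int]]) -> dict[str, float]:
    """Pool TP/FP/FN across classes, then apply the P/R/F formulas."""
    if not counts:
        raise ValueError("micro-averaging needs at least one class")
    tp = sum(c[0] for c in counts.values())
    fp = sum(c[1] for c in counts.values())
    fn = sum(c[2] for c in counts.values())
    return prf(tp, fp, fn)


@dataclass
class EvalReport:
    """Per-class strict-span counts and scores plus the micro average."""

    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    token_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def per_class(self) -> dict[str, dict[str, float]]:
        return {cls: prf(*c) for cls, c in self.counts.items()}

    @property
    def micro(self) -> dict[str, float]:
        return micro(self.counts)

    def to_dict(self) -> dict:
        return {
            "classes": {
                cls: {"TP": c[0], "FP": c[1], "FN": c[2], **prf(*c)}
                for cls, c in sorted(self.counts.items())
            },
            "token_classes": {
                cls: {"TP": c[0], "FP": c[1], "FN": c[2], **prf(*c)}
                for cls, c in sorted(self.token_counts.items())
            },
            "micro": self.micro,
        }

    def to_tsv(self) -> str:
        lines = ["class\tTP\tFP\tFN\tP\tR\tF"]
        for cls, c in sorted(self.counts.items()):
            s = prf(*c)
            lines.append(f"{cls}\t{c[0]}\t{c[1]}\t{c[2]}\t{s['P']}\t{s['R']}\t{s['F']}")
        m = self.micro
        lines.append(f"micro\t\t\t\t{m['P']}\t{m['R']}\t{m['F']}")
        return "\n".join(lines) + "\n"


def score_documents(
    gold_docs: list[Document],
    predictions,
    classes: tuple[str, ...] = ("explicit", "implicit"),
) -> EvalReport:
    """Score pipeline results against gold anatomy spans, per class.

    ``predictions`` aligns with ``gold_docs`` and provides
    ``explicit_spans`` / ``implicit_spans`` (a
    :class:`~anatomyner.recognizers.PipelineResult` or duck-typed
    equivalent).
    """
    report = EvalReport()
    for cls in classes:
        tp = fp = fn = 0
        ttp = tfp = tfn = 0
        for doc, res in zip(gold_docs, predictions):
            gold = [sp for sp in doc.anatomy_spans if sp.label == cls]
            pred = getattr(res, f"{cls}_spans")
            a, b, c = strict_match(gold, pred)
            tp, fp, fn = tp + a, fp + b, fn + c
            a, b, c = token_match(gold, pred)
            ttp, tfp, tfn = ttp + a, tfp + b, tfn + c
        report.counts[cls] = (tp, fp, fn)
        report.token_counts[cls] = (ttp, tfp, tfn)
    return report


# ---------------------------------------------------------------------------
# Inter-annotator agreement


def kappa(
    tags_a: list[list[str]],
    tags_b: list[list[str]],
    positive=lambda tag: tag != "O",
) -> float | None:
    """Cohen's kappa over token-level binary (entity vs O) decisions.

    ``k = (po - pe) / (1 - pe)`` with observed agreement ``po`` and the
    chance agreement ``pe`` implied by each annotator's marginals.
    Returns ``None`` (undefined) when ``pe = 1``; returns 1.0 for
    identical annotations.
    """
    flat_a = [positive(t) for seq in tags_a for t in seq]
    flat_b = [positive(t) for seq in tags_b for t in seq]
    if len(flat_a) != len(flat_b):
        raise ValueError(
            f"annotation lengths differ: {len(flat_a)} vs {len(flat_b)}"
        )
    n = len(flat_a)
    if n == 0:
        raise ValueError("cannot compute kappa on empty annotations")
    a = np.asarray(flat_a, dtype=bool)
    b = np.asarray(flat_b, dtype=bool)
    po = float(np.mean(a == b))
    if po == 1.0:
        return 1.0
    pa, pb = float(a.mean()), float(b.mean())
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return None
    return (po - pe) / (1 - pe)


# ---------------------------------------------------------------------------
# Experiment reports


def ablation_report(
    docs: list[Document],
    configs: list[tuple[str, "PipelineConfig"]],
    k: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Cross-validated scores per named config, with increments vs the first.

    The first config is the baseline; each row carries per-class P/R/F,
    the micro average, and ``Inc`` columns = F(config) - F(baseline),
    rounded to four decimals.  Deterministic given the seed.
    """
    from .recognizers import crossval  # local import avoids a cycle

    rows = []
    for name, config in configs:
        cv = crossval(docs, k=k, config=config, seed=seed)
        report = score_documents(docs, cv["predictions"])
        rows.append({"name": name, "report": report})
    return attach_increments(rows)


def increment(f_config: float, f_baseline: float) -> float:
    """Ablation increment: F(config) - F(baseline), rounded to 4 dp."""
    return round(f_config - f_baseline, ROUND)


def attach_increments(rows: list[dict]) -> list[dict]:
    """Add per-class and micro F increments relative to the first row."""
    if not rows:
        return rows
    base = rows[0]["report"]
    base_f = {cls: s["F"] for cls, s in base.per_class.items()}
    base_micro = base.micro["F"]
    out = []
    for row in rows:
        rep = row["report"]
        entry = {"name": row["name"], "classes": rep.per_class, "micro": rep.micro}
        entry["inc"] = {
            cls: increment(s["F"], base_f.get(cls, 0.0))
            for cls, s in rep.per_class.items()
        }
        entry["inc"]["micro"] = increment(rep.micro["F"], base_micro)
        out.append(entry)
    return out


def learning_curve(
    docs: list[Document],
    sizes: list[int],
    config: "PipelineConfig",
    k: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Cross-validated performance at seeded document subsamples.

    Each size draws a seeded subsample of the corpus and runs the same
    k-fold protocol on it; the full-corpus size therefore coincides with
    plain cross-validation.
    """
    from .recognizers import crossval

    rng = np.random.default_rng(seed)
    out = []
    for size in sizes:
        if size > len(docs):
            raise ValueError(f"size {size} exceeds corpus size {len(docs)}")
        if size == len(docs):
            subset = list(docs)
        else:
            idx = np.sort(rng.choice(len(docs), size=size, replace=False))
            subset = [docs[int(i)] for i in idx]
        cv = crossval(subset, k=k, config=config, seed=seed)
        report = score_documents(subset, cv["predictions"])
        out.append({"size": size, "report": report})
    return out
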