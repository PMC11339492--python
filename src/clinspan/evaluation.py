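"""Exact- and relaxed-match NER scoring and error categorization.

Follows the 2010 i2b2 concept-extraction conventions: an exact match
requires identical span boundaries and entity type; a relaxed match
requires the same type and any character overlap with a gold span.
Overall scores are micro-averaged (pooled TP/FP/FN counts across labels);
macro averages are also exposed.

Counting is match-existence based: a prediction overlapping two golds of
its label counts as one true positive for precision, and each overlapped
gold counts as recalled. The alternative one-to-one matching can be swapped
in via :func:`categorize_errors`, which pairs spans greedily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .corpus import Corpus, Document, Entity

MODES = ("exact", "relaxed")


class EvaluationError(ValueError):
    pass


def match_exact(gold: Entity, pred: Entity) -> bool:
    """Identical boundaries and identical type."""
    return (
        gold.start == pred.start
        and gold.end == pred.end
        and gold.label == pred.label
    )


def match_relaxed(gold: Entity, pred: Entity) -> bool:
    """Same type and at least one character of overlap (half-open spans)."""
    return gold.label == pred.label and gold.start < pred.end and pred.start < gold.end


_MATCHERS = {"exact": match_exact, "relaxed": match_relaxed}


@dataclass
class LabelScores:
    n_gold: int = 0
    n_pred: int = 0
    tp_gold: int = 0  # golds matched by >=1 prediction
    tp_pred: int = 0  # predictions matched by >=1 gold

    @property
    def precision(self) -> float:
        return self.tp_pred / self.n_pred if self.n_pred else 0.0

    @property
    def recall(self) -> float:
        return self.tp_gold / self.n_gold if self.n_gold else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class ScoreReport:
    mode: str
    per_label: dict[str, LabelScores]
    overall: LabelScores
    undefined: set[str] = field(default_factory=set)  # labels with empty denominators

    @property
    def macro_precision(self) -> float:
        ls = list(self.per_label.values())
        return sum(s.precision for s in ls) / len(ls) if ls else 0.0

    @property
    def macro_recall(self) -> float:
        ls = list(self.per_label.values())
        return sum(s.recall for s in ls) / len(ls) if ls else 0.0

    @property
    def macro_f1(self) -> float:
        ls = list(self.per_label.values())
        return sum(s.f1 for s in ls) / len(ls) if ls else 0.0

    def to_dict(self) -> dict:
        def row(s: LabelScores) -> dict:
            return {
                "n_gold": s.n_gold,
                "n_pred": s.n_pred,
                "tp_gold": s.tp_gold,
                "tp_pred": s.tp_pred,
                "precision": s.precision,
                "recall": s.recall,
                "f1": s.f1,
            }

        return {
            "mode": self.mode,
            "overall": row(self.overall),
            "per_label": {lab: row(s) for lab, s in sorted(self.per_label.items())},
            "undefined": sorted(self.undefined),
        }


def score(
    gold_corpus: Corpus,
    predictions: dict[str, list[Entity]],
    mode: str = "exact",
) -> ScoreReport:
    """Score *predictions* (keyed by doc_id) against the gold corpus.

    Documents absent from *predictions* count as zero predictions; a
    prediction doc_id absent from the corpus is an error.
    """
    if mode not in _MATCHERS:
        raise EvaluationError(f"unknown mode {mode!r}; expected one of {MODES}")
    matcher = _MATCHERS[mode]
    gold_ids = {d.doc_id for d in gold_corpus}
    for doc_id in predictions:
        if doc_id not in gold_ids:
            raise EvaluationError(f"prediction doc_id {doc_id!r} not in corpus")

    per_label = {lab: LabelScores() for lab in gold_corpus.labels}
    for doc in gold_corpus:
        preds = predictions.get(doc.doc_id, [])
        for p in preds:
            if p.label not in per_label:
                per_label[p.label] = LabelScores()
            per_label[p.label].n_pred += 1
            if any(matcher(g, p) for g in doc.entities):
                per_label[p.label].tp_pred += 1
        for g in doc.entities:
            per_label[g.label].n_gold += 1
            if any(matcher(g, p) for p in preds):
                per_label[g.label].tp_gold += 1

    overall = LabelScores(
        n_gold=sum(s.n_gold for s in per_label.values()),
        n_pred=sum(s.n_pred for s in per_label.values()),
        tp_gold=sum(s.tp_gold for s in per_label.values()),
        tp_pred=sum(s.tp_pred for s in per_label.values()),
    )
    undefined = {
        lab for lab, s in per_label.items() if s.n_pred == 0 or s.n_gold == 0
    }
    return ScoreReport(mode, per_label, overall, undefined)


ERROR_KINDS = ("boundary_only", "type_only", "boundary_and_type", "missing", "spurious")


@dataclass
class ErrorBreakdown:
    """Counts of non-exact prediction/gold discrepancies."""

    boundary_only: int = 0
    type_only: int = 0
    boundary_and_type: int = 0
    missing: int = 0
    spurious: int = 0

    @property
    def total(self) -> int:
        return sum(getattr(self, k) for k in ERROR_KINDS)

    def percentages(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {k: 0.0 for k in ERROR_KINDS}
        return {k: 100.0 * getattr(self, k) / t for k in ERROR_KINDS}

    def __add__(self, other: "ErrorBreakdown") -> "ErrorBreakdown":
        return ErrorBreakdown(
            *[getattr(self, k) + getattr(other, k) for k in ERROR_KINDS]
        )

    def to_dict(self) -> dict:
        return {
            "counts": {k: getattr(self, k) for k in ERROR_KINDS},
            "percentages": self.percentages(),
            "total": self.total,
        }


def categorize_errors(gold_doc: Document, preds: list[Entity]) -> ErrorBreakdown:
    """Categorize non-exact discrepancies for one document.

    Exact matches are paired first (one-to-one) and excluded. Remaining
    predictions are paired greedily left-to-right with the first unpaired
    overlapping gold: same label -> boundary_only; same span, other label ->
    type_only; otherwise boundary_and_type. Unpaired golds are missing,
    unpaired predictions spurious.
    """
    golds = list(gold_doc.entities)
    rem_preds = []
    for p in sorted(preds):
        hit = next((g for g in golds if match_exact(g, p)), None)
        if hit is not None:
            golds.remove(hit)
        else:
            rem_preds.append(p)
    bd = ErrorBreakdown()
    for p in rem_preds:
        hit = next(
            (g for g in sorted(golds) if g.start < p.end and p.start < g.end), None
        )
        if hit is None:
            bd.spurious += 1
            continue
        golds.remove(hit)
        same_span = hit.start == p.start and hit.end == p.end
        same_label = hit.label == p.label
        if same_label:
            bd.boundary_only += 1
        elif same_span:
            bd.type_only += 1
        else:
            bd.boundary_and_type += 1
    bd.missing += len(golds)
    return bd


def categorize_corpus_errors(
    gold_corpus: Corpus, predictions: dict[str, list[Entity]]
) -> ErrorBreakdown:
    """Aggregate :func:`categorize_errors` over a whole corpus."""
    total = ErrorBreakdown()
    for doc in gold_corpus:
        total = total + categorize_errors(doc, predictions.get(doc.doc_id, []))
    return total


def compare_runs(report_a: ScoreReport, report_b: ScoreReport) -> pd.DataFrame:
    """Per-label and overall P/R/F1 deltas (B minus A) between two runs."""
    if report_a.mode != report_b.mode:
        raise EvaluationError(
            f"mode mismatch: {report_a.mode!r} vs {report_b.mode!r}"
        )
    rows = []
    labels = sorted(set(report_a.per_label) | set(report_b.per_label))
    for lab in labels + ["overall"]:
        a = report_a.overall if lab == "overall" else report_a.per_label.get(lab, LabelScores())
        b = report_b.overall if lab == "overall" else report_b.per_label.get(lab, LabelScores())
        rows.append(
            {
                "label": lab,
                "delta_precision": b.precision - a.precision,
                "delta_recall": b.recall - a.recall,
                "delta_f1": b.f1 - a.f1,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def format_report_table(reports: dict[str, ScoreReport]) -> str:
    """Aligned plain-text table with P/R/F1 columns per mode."""
    modes = list(reports)
    labels = sorted({lab for r in reports.values() for lab in r.per_label})
    header = ["label".ljust(24)] + [
        f"{m}-P    {m}-R    {m}-F1 ".ljust(24) for m in modes
    ]
    lines = ["".join(header)]
    for lab in labels + ["overall"]:
        cells = [lab.ljust(24)]
        for m in modes:
            r = reports[m]
            s = r.overall if lab == "overall" else r.per_label.get(lab, LabelScores())
            cells.append(
                f"{s.precision:.3f}  {s.recall:.3f}  {s.f1:.3f}".ljust(24)
            )
        lines.append("".join(cells))
    return "\n".join(lines)
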