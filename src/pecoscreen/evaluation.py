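"""Scoring screened decisions against gold inclusion labels.

A screened-in reference that the review actually included is a true
positive; screened-in but not included, a false positive; screened-out but
included, a false negative (the costly error — it would never be seen by a
human); screened-out and not included, a true negative.

Workload metrics, with N the number of abstract-bearing references:

* ``work_saved     = 1 - (TP + FP) / N`` — the fraction of records a human
  no longer screens manually (everything flagged positive still goes to a
  human);
* ``max_work_saved = 1 - I / N`` — the ceiling attained by a perfect
  screener that flags exactly the I truly included records.

All ratios are held as exact rationals and only rounded for display:
precision and recall at integer percent, work saved at one decimal.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Iterable, Sequence, TextIO

from .extractor import CharacteristicProfile
from .reference_io import Corpus, GoldLabels
from .screening import ScreeningRule, screen_corpus


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclasses.dataclass(frozen=True)
class Metrics:
    """Derived screening metrics; ratios are exact Fractions.

    ``precision`` is None (rendered "n/a") when nothing was flagged;
    ``recall`` is None when the gold set is empty.
    """

    precision: Fraction | None
    recall: Fraction | None
    work_saved: Fraction
    max_work_saved: Fraction
    n: int
    n_included: int

    @staticmethod
    def _pct(x: Fraction | None, decimals: int) -> str:
        if x is None:
            return "n/a"
        return f"{float(100 * x):.{decimals}f}%" if decimals else f"{round(100 * x)}%"

    @property
    def precision_str(self) -> str:
        return self._pct(self.precision, 0)

    @property
    def recall_str(self) -> str:
        return self._pct(self.recall, 0)

    @property
    def work_saved_str(self) -> str:
        return self._pct(self.work_saved, 1)

    @property
    def max_work_saved_str(self) -> str:
        return self._pct(self.max_work_saved, 1)


def confusion(
    included_ids: set[str], gold: GoldLabels, universe: set[str]
) -> ConfusionMatrix:
    """Classify every reference in the universe against the gold labels."""
    gold.validate_against(universe)
    stray = sorted(included_ids - universe)
    if stray:
        raise ValueError(f"screened-in IDs absent from universe: {', '.join(stray)}")
    g = gold.included_ids
    return ConfusionMatrix(
        tp=len(included_ids & g),
        fp=len(included_ids - g),
        fn=len(g - included_ids),
        tn=len(universe - (included_ids | g)),
    )


def metrics(cm: ConfusionMatrix, n_included: int | None = None) -> Metrics:
    """Precision, recall and workload savings from a confusion matrix.

    ``n_included`` defaults to tp + fn; passing it explicitly allows a
    sanity check when the gold count is known independently.
    """
    if cm.n == 0:
        raise ValueError("cannot compute metrics over an empty universe")
    if n_included is None:
        n_included = cm.tp + cm.fn
    elif n_included != cm.tp + cm.fn:
        raise ValueError(
            f"n_included={n_included} inconsistent with tp+fn={cm.tp + cm.fn}"
        )
    flagged = cm.tp + cm.fp
    return Metrics(
        precision=Fraction(cm.tp, flagged) if flagged else None,
        recall=Fraction(cm.tp, n_included) if n_included else None,
        work_saved=1 - Fraction(flagged, cm.n),
        max_work_saved=1 - Fraction(n_included, cm.n),
        n=cm.n,
        n_included=n_included,
    )


@dataclasses.dataclass(frozen=True)
class ReportCell:
    corpus_name: str
    rule_name: str
    cm: ConfusionMatrix
    metrics: Metrics


POOLED_NAME = "Average"


@dataclasses.dataclass
class EvaluationReport:
    """Grid of (corpus × rule) results plus a micro-averaged pooled row.

    Pooling sums confusion cells across corpora before recomputing
    metrics, so pooled cells always equal the sum of per-corpus cells.
    """

    cells: list[ReportCell]
    corpus_names: list[str]
    rule_names: list[str]

    def cell(self, corpus_name: str, rule_name: str) -> ReportCell:
        for c in self.cells:
            if c.corpus_name == corpus_name and c.rule_name == rule_name:
                return c
        raise KeyError((corpus_name, rule_name))

    def to_tsv(self, stream: TextIO) -> None:
        stream.write(
            "corpus\trule\ttp\tfp\tfn\ttn\tprecision\trecall\t"
            "work_saved\tmax_work_saved\n"
        )
        for c in self.cells:
            m = c.metrics
            stream.write(
                f"{c.corpus_name}\t{c.rule_name}\t{c.cm.tp}\t{c.cm.fp}\t"
                f"{c.cm.fn}\t{c.cm.tn}\t{m.precision_str}\t{m.recall_str}\t"
                f"{m.work_saved_str}\t{m.max_work_saved_str}\n"
            )

    def to_text(self, stream: TextIO) -> None:
        """Aligned plain-text table, one block per corpus."""
        header = (
            f"{'rule':<22}{'TP':>6}{'FP':>6}{'FN':>6}{'TN':>8}"
            f"{'Pr':>7}{'Re':>7}{'Work saved':>12}"
        )
        for corpus_name in self.corpus_names + [POOLED_NAME]:
            block = [c for c in self.cells if c.corpus_name == corpus_name]
            if not block:
                continue
            m0 = block[0].metrics
            # the corpus has one gold count; if rows disagree on tp+fn the
            # smallest is the defensible ceiling (extra "gold" inflates it)
            best = min(block, key=lambda c: c.metrics.n_included).metrics
            stream.write(
                f"{corpus_name} (n = {m0.n} articles)  "
                f"Max = {best.max_work_saved_str}\n"
            )
            stream.write(header + "\n")
            for c in block:
                m = c.metrics
                stream.write(
                    f"{c.rule_name:<22}{c.cm.tp:>6}{c.cm.fp:>6}{c.cm.fn:>6}"
                    f"{c.cm.tn:>8}{m.precision_str:>7}{m.recall_str:>7}"
                    f"{m.work_saved_str:>12}\n"
                )
            stream.write("\n")


def build_report(
    corpora: Sequence[tuple[Corpus, GoldLabels, Sequence[CharacteristicProfile]]],
    rules: Sequence[ScreeningRule],
) -> EvaluationReport:
    """Screen every corpus under every rule and assemble the full grid."""
    if not corpora or not rules:
        raise ValueError("need at least one corpus and one rule")
    cells: list[ReportCell] = []
    pooled: dict[str, ConfusionMatrix] = {}
    for corpus, gold, profiles in corpora:
        universe = {p.ref_id for p in profiles}
        for rule in rules:
            included, _ = screen_corpus(list(profiles), rule)
            cm = confusion(included, gold, universe)
            cells.append(ReportCell(corpus.name, rule.name, cm, metrics(cm)))
            pooled[rule.name] = pooled.get(
                rule.name, ConfusionMatrix(0, 0, 0, 0)
            ) + cm
    for rule in rules:
        cm = pooled[rule.name]
        cells.append(ReportCell(POOLED_NAME, rule.name, cm, metrics(cm)))
    return EvaluationReport(
        cells=cells,
        corpus_names=[c.name for c, _, _ in corpora],
        rule_names=[r.name for r in rules],
    )


def report_from_counts(
    counts: Iterable[tuple[str, str, ConfusionMatrix]],
    rule_names: Sequence[str] | None = None,
) -> EvaluationReport:
    """Build a report directly from per-(corpus, rule) confusion cells.

    Used when the confusion counts are themselves the input — e.g.
    re-deriving the metric columns of a published results table from its
    printed TP/FP/FN/TN cells. Pooled cells are summed per rule, but only
    for rules every corpus contributed (a partial pool would misstate the
    average).
    """
    counts = list(counts)
    if not counts:
        raise ValueError("no counts given")
    corpus_names: list[str] = []
    seen_rules: list[str] = []
    pooled: dict[str, ConfusionMatrix] = {}
    contributors: dict[str, int] = {}
    cells = []
    for corpus_name, rule_name, cm in counts:
        if corpus_name not in corpus_names:
            corpus_names.append(corpus_name)
        if rule_name not in seen_rules:
            seen_rules.append(rule_name)
        cells.append(ReportCell(corpus_name, rule_name, cm, metrics(cm)))
        pooled[rule_name] = pooled.get(rule_name, ConfusionMatrix(0, 0, 0, 0)) + cm
        contributors[rule_name] = contributors.get(rule_name, 0) + 1
    order = list(rule_names) if rule_names is not None else seen_rules
    for rule_name in order:
        if contributors.get(rule_name, 0) == len(corpus_names):
            cm = pooled[rule_name]
            cells.append(ReportCell(POOLED_NAME, rule_name, cm, metrics(cm)))
    return EvaluationReport(cells, corpus_names, order)
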