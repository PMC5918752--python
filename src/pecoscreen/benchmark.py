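"""Published benchmark confusion counts for the three evaluation reviews.

The package ships the per-(review, rule) TP/FP/FN/TN cells reported by a
published evaluation of characteristic-based screening on three
environmental-health systematic reviews (Hamra 2014, particulate matter
and lung cancer; Johnson 2014, PFOA and fetal growth; Thayer 2013, BPA and
obesity). Re-deriving the metric columns from these cells through
:mod:`pecoscreen.evaluation` reproduces the headline workload-savings
numbers — e.g. the pooled EO rule saving 93.7% of screening work at 98%
recall.

Only internally consistent rows are shipped (see the data file header);
rules whose rows survive for all three reviews (Any3, Any2, EO) also get a
pooled micro-averaged row.
"""

from __future__ import annotations

from importlib import resources

from .evaluation import ConfusionMatrix, EvaluationReport, report_from_counts

_DATA = "data/reported_screening_counts.tsv"

#: Rule display order matching the source table.
RULE_ORDER = ("All4", "Any3", "Any2", "PEO", "PE", "EO")


def load_reported_counts() -> list[tuple[str, str, ConfusionMatrix]]:
    """Load the shipped (review, rule, confusion-cells) rows."""
    text = (
        resources.files("pecoscreen").joinpath(_DATA).read_text("utf-8")
    )
    rows: list[tuple[str, str, ConfusionMatrix]] = []
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        review, rule, tp, fp, fn, tn = line.split("\t")
        rows.append(
            (review, rule, ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
        )
    return rows


def reported_report() -> EvaluationReport:
    """The benchmark grid with metrics recomputed from the shipped cells."""
    return report_from_counts(load_reported_counts(), rule_names=RULE_ORDER)
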