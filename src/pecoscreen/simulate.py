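"""Synthetic abstract corpora with planted characteristic mentions.

The generator emulates the structure that matters to threshold screening:
each synthetic reference is truly included with a small prevalence, and its
abstract mentions each study characteristic independently with a
class-conditional probability (included articles mention exposure and
outcome almost always, confounders least — abstracts routinely omit them).
A planted mention uses an in-lexicon phrase, or — with probability
``vocab_miss_rate`` — an out-of-lexicon synonym, reproducing the real
failure mode of dictionary-based extraction: an abstract that says "PFC"
and "maternal cord blood" where the dictionary knows "PFOA" and "pregnant
women" is invisible to the extractor and becomes a false negative no
screening rule can recover.

Because mentions are planted independently per characteristic, the
operating point of any k-of-S rule has an exact closed form
(:func:`expected_operating_point`), against which Monte-Carlo pipeline
runs can be checked. Corpora are emitted through the real RIS/gold-label
I/O path so end-to-end runs exercise the same plumbing as real exports.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
from pathlib import Path
from typing import Mapping, TextIO

import numpy as np

from .characteristics import CHARACTERISTIC_ORDER, Characteristic
from .lexicons import LexiconSet, normalize_phrase
from .reference_io import Corpus, GoldLabels, Reference
from .screening import ScreeningRule


class Mention(str, enum.Enum):
    NONE = "none"
    IN_LEXICON = "in_lexicon"
    OUT_OF_LEXICON = "out_of_lexicon"


#: Phrase bank modelled on a perfluorinated-compound / fetal-growth review
#: topic. For each characteristic: phrases the demonstration lexicons know,
#: and out-of-dictionary synonyms a real abstract might use instead.
DEFAULT_PHRASE_BANK: dict[Characteristic, tuple[tuple[str, ...], tuple[str, ...]]] = {
    Characteristic.POPULATION: (
        ("pregnant women", "infants", "school-age children"),
        ("maternal cord blood", "expectant mothers"),
    ),
    Characteristic.EXPOSURE: (
        ("PFOA", "PFOS", "perfluorooctanoic acid"),
        ("PFC", "perfluorinated chemicals"),
    ),
    Characteristic.CONFOUNDER: (
        ("maternal age", "smoking"),
        ("parity", "gestational duration"),
    ),
    Characteristic.OUTCOME: (
        ("birth weight", "fetal growth"),
        ("neonatal anthropometry", "ponderal index"),
    ),
    Characteristic.COUNTRY: (
        ("Denmark", "Japan"),
        ("the Faroe Islands",),
    ),
    Characteristic.STUDY_TYPE: (
        ("cohort study", "case-control study"),
        ("longitudinal panel",),
    ),
}

#: Neutral filler sentences: no numerals, no person-class terms, no
#: adjustment language, and no vocabulary shared with the phrase bank —
#: so filler can never create a characteristic hit.
DEFAULT_FILLER_BANK: tuple[str, ...] = (
    "The laboratory protocol was reviewed by an independent committee.",
    "Sampling procedures followed the approved institutional guidelines.",
    "Data management relied on a secure electronic archive.",
    "Statistical software was used for all computations.",
    "Ethical approval was obtained prior to data collection.",
    "Measurement devices were calibrated at regular intervals.",
    "Quality assurance checks were performed throughout the project.",
    "The funding body had no role in the interpretation of findings.",
    "Further methodological details are available upon request.",
    "Analytical pipelines were documented for reproducibility.",
)

#: Neutral carrier sentences for planted phrases (same constraints as filler).
_CARRIERS: tuple[str, ...] = (
    "The investigation considered {phrase} in detail.",
    "Particular attention was given to {phrase}.",
    "Assessment of {phrase} formed a central part of the design.",
    "Findings concerning {phrase} are summarised here.",
)

#: Probability that a reference with planted mentions repeats one of its
#: planted phrases in the title, exercising title matching.
TITLE_PLANT_PROB = 0.3

_DEFAULT_P_INCLUDED = {
    Characteristic.POPULATION: 0.70,
    Characteristic.EXPOSURE: 0.97,
    Characteristic.CONFOUNDER: 0.45,
    Characteristic.OUTCOME: 0.97,
    Characteristic.COUNTRY: 0.60,
    Characteristic.STUDY_TYPE: 0.50,
}
_DEFAULT_P_EXCLUDED = {
    Characteristic.POPULATION: 0.25,
    Characteristic.EXPOSURE: 0.20,
    Characteristic.CONFOUNDER: 0.08,
    Characteristic.OUTCOME: 0.25,
    Characteristic.COUNTRY: 0.30,
    Characteristic.STUDY_TYPE: 0.20,
}


@dataclasses.dataclass
class SimulationParams:
    """Generator knobs; the defaults mirror the evaluation-study setting.

    ``prevalence`` defaults to 1% — the three benchmark reviews included
    0.6–2.7% of retrieved references. Mention probabilities are
    class-conditional (included vs excluded) and per characteristic;
    ``vocab_miss_rate`` defaults to 0.02, of the order of the one
    dictionary miss among 45 included studies observed in practice.
    """

    n_refs: int = 2000
    prevalence: float = 0.01
    p_mention_included: Mapping[Characteristic, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_P_INCLUDED)
    )
    p_mention_excluded: Mapping[Characteristic, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_P_EXCLUDED)
    )
    vocab_miss_rate: float = 0.02
    seed: int = 0
    corpus_name: str = "synthetic"
    phrase_bank: Mapping[
        Characteristic, tuple[tuple[str, ...], tuple[str, ...]]
    ] = dataclasses.field(default_factory=lambda: dict(DEFAULT_PHRASE_BANK))
    filler_bank: tuple[str, ...] = DEFAULT_FILLER_BANK

    def __post_init__(self) -> None:
        if self.n_refs < 0:
            raise ValueError("n_refs must be >= 0")
        probs = [self.prevalence, self.vocab_miss_rate]
        probs += list(self.p_mention_included.values())
        probs += list(self.p_mention_excluded.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for c in Characteristic:
            in_lex, out_lex = self.phrase_bank.get(c, ((), ()))
            needed = max(
                self.p_mention_included.get(c, 0.0),
                self.p_mention_excluded.get(c, 0.0),
            )
            if needed > 0 and not in_lex:
                raise ValueError(
                    f"positive mention probability for {c.value} but its "
                    "in-lexicon phrase bank is empty"
                )
            in_norm = {normalize_phrase(p) for p in in_lex}
            out_norm = {normalize_phrase(p) for p in out_lex}
            if in_norm & out_norm:
                raise ValueError(
                    f"in- and out-of-lexicon banks overlap for {c.value}"
                )
            if needed > 0 and self.vocab_miss_rate > 0 and not out_lex:
                raise ValueError(
                    f"vocab_miss_rate > 0 but no out-of-lexicon synonyms "
                    f"for {c.value}"
                )

    def lexicon_set(self) -> LexiconSet:
        """The matching lexicons: exactly the in-lexicon phrase banks."""
        return LexiconSet.from_phrase_map(
            {c: list(self.phrase_bank.get(c, ((), ()))[0]) for c in Characteristic},
            provenance="synthetic phrase bank",
        )


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth for every generated reference."""

    verdicts: dict[str, bool]  # ref_id -> truly included
    mentions: dict[str, dict[Characteristic, Mention]]
    planted_phrases: dict[str, dict[Characteristic, str]]

    def included_ids(self) -> set[str]:
        return {rid for rid, inc in self.verdicts.items() if inc}


def generate_corpus(
    params: SimulationParams,
) -> tuple[Corpus, GoldLabels, SyntheticTruth]:
    """Generate a labelled corpus; byte-identical for identical params."""
    rng = np.random.default_rng(params.seed)
    refs: list[Reference] = []
    verdicts: dict[str, bool] = {}
    mentions: dict[str, dict[Characteristic, Mention]] = {}
    planted: dict[str, dict[Characteristic, str]] = {}

    for i in range(params.n_refs):
        ref_id = f"{params.corpus_name}-{i:05d}"
        included = bool(rng.random() < params.prevalence)
        p_map = (
            params.p_mention_included if included else params.p_mention_excluded
        )
        ref_mentions: dict[Characteristic, Mention] = {}
        ref_phrases: dict[Characteristic, str] = {}
        planted_sentences: list[str] = []
        for c in CHARACTERISTIC_ORDER:
            p = p_map.get(c, 0.0)
            if rng.random() >= p:
                ref_mentions[c] = Mention.NONE
                continue
            in_lex, out_lex = params.phrase_bank[c]
            if params.vocab_miss_rate > 0 and rng.random() < params.vocab_miss_rate:
                ref_mentions[c] = Mention.OUT_OF_LEXICON
                phrase = out_lex[rng.integers(len(out_lex))]
            else:
                ref_mentions[c] = Mention.IN_LEXICON
                phrase = in_lex[rng.integers(len(in_lex))]
            ref_phrases[c] = phrase
            carrier = _CARRIERS[rng.integers(len(_CARRIERS))]
            planted_sentences.append(carrier.format(phrase=phrase))

        n_filler = int(rng.integers(3, 7))
        filler_idx = rng.permutation(len(params.filler_bank))[:n_filler]
        sentences = [params.filler_bank[j] for j in filler_idx]
        for sentence in planted_sentences:
            pos = int(rng.integers(len(sentences) + 1))
            sentences.insert(pos, sentence)
        abstract = " ".join(sentences)

        # planted phrase goes BEFORE the record number: a person-class term
        # following a numeral would fire the population pattern spuriously
        title = f"Synthetic record {i:05d}"
        if ref_phrases and rng.random() < TITLE_PLANT_PROB:
            title_chars = sorted(ref_phrases, key=lambda c: c.value)
            c_title = title_chars[rng.integers(len(title_chars))]
            title = f"{ref_phrases[c_title]}: synthetic record {i:05d}"

        year = int(2005 + rng.integers(11))
        refs.append(
            Reference(
                ref_id=ref_id,
                title=title,
                abstract=abstract,
                year=year,
                source="synthetic",
                raw={
                    "TY": ["JOUR"],
                    "AN": [ref_id],
                    "TI": [title],
                    "AB": [abstract],
                    "PY": [str(year)],
                },
            )
        )
        verdicts[ref_id] = included
        mentions[ref_id] = ref_mentions
        planted[ref_id] = ref_phrases

    corpus = Corpus(
        name=params.corpus_name,
        references=refs,
        n_total=params.n_refs,
        n_with_abstract=params.n_refs,
    )
    truth = SyntheticTruth(verdicts, mentions, planted)
    gold = GoldLabels(truth.included_ids(), review_name=params.corpus_name)
    return corpus, gold, truth


def _p_at_least_k(qs: list[float], k: int) -> float:
    """P(at least k of the independent Bernoulli(q) succeed), by enumeration."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=len(qs)):
        if sum(outcome) < k:
            continue
        prob = 1.0
        for q, hit in zip(qs, outcome):
            prob *= q if hit else 1.0 - q
        total += prob
    return total


def expected_operating_point(
    params: SimulationParams, rule: ScreeningRule
) -> tuple[float, float]:
    """Closed-form (expected recall, expected fraction flagged) for a rule.

    Each characteristic in the rule's set is hit with effective probability
    ``q_c = p_mention[c] * (1 - vocab_miss_rate)``; hits are independent, so
    the rule's pass probability is an exact Poisson-binomial tail evaluated
    by enumeration over the at most 2^4 outcomes.
    """
    eff = 1.0 - params.vocab_miss_rate
    chars = sorted(rule.char_set, key=lambda c: c.value)
    q_inc = [params.p_mention_included.get(c, 0.0) * eff for c in chars]
    q_exc = [params.p_mention_excluded.get(c, 0.0) * eff for c in chars]
    recall = _p_at_least_k(q_inc, rule.min_hits)
    flag_rate = (
        params.prevalence * recall
        + (1.0 - params.prevalence) * _p_at_least_k(q_exc, rule.min_hits)
    )
    return recall, flag_rate


def write_truth(truth: SyntheticTruth, stream: TextIO) -> None:
    """Truth TSV: gold verdict plus per-characteristic planting decision."""
    cols = "\t".join(c.value for c in CHARACTERISTIC_ORDER)
    stream.write(f"ref_id\tincluded\t{cols}\n")
    for ref_id in sorted(truth.verdicts):
        cells = "\t".join(
            truth.mentions[ref_id][c].value for c in CHARACTERISTIC_ORDER
        )
        stream.write(
            f"{ref_id}\t{int(truth.verdicts[ref_id])}\t{cells}\n"
        )


def write_corpus_files(
    params: SimulationParams, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Generate and emit RIS + gold-label + truth files; returns the paths."""
    from .reference_io import write_gold_labels, write_ris

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus, gold, truth = generate_corpus(params)
    ris_path = out / f"{params.corpus_name}.ris"
    gold_path = out / f"{params.corpus_name}.gold.txt"
    truth_path = out / f"{params.corpus_name}.truth.tsv"
    with ris_path.open("w", encoding="utf-8") as fh:
        write_ris(corpus.references, fh)
    with gold_path.open("w", encoding="utf-8") as fh:
        write_gold_labels(gold, fh)
    with truth_path.open("w", encoding="utf-8") as fh:
        write_truth(truth, fh)
    return ris_path, gold_path, truth_path
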