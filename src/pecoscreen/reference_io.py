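"""Parsing, de-duplication and filtering of bibliographic reference exports.

Supports the two line-tagged formats reference managers and PubMed emit:

* RIS — ``XX  - value`` lines, ``TY`` opens a record, ``ER`` closes it;
* MEDLINE — 4-character tag padded with spaces, ``- ``, value; continuation
  lines are indented and belong to the preceding tag; a blank line separates
  records.

The cleaning pipeline mirrors standard systematic-review data preparation:
duplicates are removed first, then references without abstracts (which
cannot be screened on title/abstract) are set aside — reported, never
silently dropped.
"""

from __future__ import annotations

import dataclasses
import io
import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence, TextIO


class RisParseError(ValueError):
    """Structural parse failure (e.g. a record never closed by ``ER``)."""


@dataclasses.dataclass
class RecordError:
    """A record-level problem that did not stop parsing."""

    index: int  # 0-based record index in the stream
    message: str


@dataclasses.dataclass
class Reference:
    """One bibliographic record (title + abstract plus preserved raw tags).

    ``raw`` maps each tag to the list of values seen, in input order, so a
    parse → serialise → parse cycle preserves the field multiset.
    """

    ref_id: str
    title: str
    abstract: str = ""
    year: int | None = None
    authors: list[str] = dataclasses.field(default_factory=list)
    source: str = ""
    raw: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    def has_abstract(self) -> bool:
        return bool(self.abstract.strip())


@dataclasses.dataclass
class Corpus:
    """A named, cleaned collection of references ready for screening."""

    name: str
    references: list[Reference]
    n_total: int
    n_with_abstract: int

    def __post_init__(self) -> None:
        if self.n_with_abstract > self.n_total:
            raise ValueError("n_with_abstract cannot exceed n_total")
        ids = [r.ref_id for r in self.references]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ref_id within corpus")

    def ref_ids(self) -> set[str]:
        return {r.ref_id for r in self.references}


@dataclasses.dataclass
class GoldLabels:
    """The review's actual inclusion decisions, keyed by ref_id."""

    included_ids: set[str]
    review_name: str = ""

    def validate_against(self, universe: set[str]) -> None:
        missing = sorted(self.included_ids - universe)
        if missing:
            raise ValueError(
                f"gold-label IDs absent from corpus: {', '.join(missing)}"
            )


# --------------------------------------------------------------------------
# RIS
# --------------------------------------------------------------------------

_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def _open_text(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
        try:
            return io.StringIO(data.decode("utf-8"))
        except UnicodeDecodeError:  # real exports are mixed encodings
            return io.StringIO(data.decode("latin-1"))
    return source


def _normalize_title(title: str) -> str:
    return _WS.sub(" ", _PUNCT.sub("", title.casefold())).strip()


def _first(raw: dict[str, list[str]], *tags: str) -> str:
    for tag in tags:
        if raw.get(tag):
            return raw[tag][0]
    return ""


def _parse_year(text: str) -> int | None:
    m = re.search(r"\b(1[89]\d\d|20\d\d)\b", text)
    return int(m.group(1)) if m else None


def _build_reference(
    raw: dict[str, list[str]],
    source_name: str,
    seq: int,
    *,
    title_tags: Sequence[str],
    abstract_tags: Sequence[str],
    id_tags: Sequence[str],
    year_tags: Sequence[str],
    author_tags: Sequence[str],
    source_tags: Sequence[str],
) -> Reference:
    title = _WS.sub(" ", _first(raw, *title_tags)).strip()
    if not title:
        raise ValueError("record has no title")
    native_id = _first(raw, *id_tags).strip()
    ref_id = native_id if native_id else f"{source_name}:{seq:05d}"
    year = _parse_year(_first(raw, *year_tags))
    authors = [a for tag in author_tags for a in raw.get(tag, [])]
    return Reference(
        ref_id=ref_id,
        title=title,
        abstract=_WS.sub(" ", _first(raw, *abstract_tags)).strip(),
        year=year,
        authors=authors,
        source=_first(raw, *source_tags).strip(),
        raw=raw,
    )


def read_ris(
    source: str | Path | TextIO,
    source_name: str = "ris",
    errors: list[RecordError] | None = None,
) -> list[Reference]:
    """Parse RIS-dialect tagged text into references.

    ``TI``/``T1`` supply the title, ``AB``/``N2`` the abstract (absent →
    empty string); every tag is preserved in :attr:`Reference.raw`.
    A record with no ``ER  -`` terminator raises :class:`RisParseError`
    naming the byte offset where it began; a record without a title is
    collected into *errors* (or warned about) and parsing continues.
    """
    stream = _open_text(source)
    refs: list[Reference] = []
    raw: dict[str, list[str]] | None = None
    last_tag: str | None = None
    record_index = 0
    offset = 0
    record_start = 0

    def finish(raw_rec: dict[str, list[str]]) -> None:
        nonlocal record_index
        try:
            refs.append(
                _build_reference(
                    raw_rec,
                    source_name,
                    record_index,
                    title_tags=("TI", "T1"),
                    abstract_tags=("AB", "N2"),
                    id_tags=("AN", "ID"),
                    year_tags=("PY", "Y1"),
                    author_tags=("AU", "A1"),
                    source_tags=("JO", "JF", "T2"),
                )
            )
        except ValueError as exc:
            err = RecordError(record_index, str(exc))
            if errors is not None:
                errors.append(err)
            else:
                warnings.warn(f"RIS record {record_index}: {exc}", stacklevel=2)
        record_index += 1

    for line in stream:
        m = _RIS_TAG.match(line.rstrip("\n"))
        if m:
            tag, value = m.group(1), m.group(2).strip()
            if tag == "TY":
                if raw is not None:
                    raise RisParseError(
                        f"record starting at byte offset {record_start} has no "
                        f"'ER  -' terminator"
                    )
                raw = {}
                record_start = offset
            if raw is not None:
                if tag == "ER":
                    finish(raw)
                    raw = None
                    last_tag = None
                else:
                    raw.setdefault(tag, []).append(value)
                    last_tag = tag
        elif raw is not None and last_tag is not None and line.strip():
            # unindented continuation of the previous tag value
            raw[last_tag][-1] = f"{raw[last_tag][-1]} {line.strip()}"
        offset += len(line.encode("utf-8", "surrogateescape"))
    if raw is not None:
        raise RisParseError(
            f"record starting at byte offset {record_start} has no "
            f"'ER  -' terminator"
        )
    return refs


def write_ris(refs: Iterable[Reference], stream: TextIO) -> None:
    """Serialise references back to RIS, emitting preserved raw tags."""
    for ref in refs:
        raw = ref.raw or {"TY": ["JOUR"], "TI": [ref.title], "AB": [ref.abstract]}
        if "TY" not in raw:
            stream.write("TY  - JOUR\n")
        for tag, values in raw.items():
            if tag in ("TY",):
                stream.write(f"TY  - {values[0]}\n")
                continue
            for value in values:
                stream.write(f"{tag}  - {value}\n")
        stream.write("ER  - \n")


# --------------------------------------------------------------------------
# MEDLINE
# --------------------------------------------------------------------------

_MEDLINE_TAG = re.compile(r"^([A-Z][A-Z0-9]{1,3})\s*- ?(.*)$")


def read_medline(
    source: str | Path | TextIO,
    source_name: str = "medline",
    errors: list[RecordError] | None = None,
) -> list[Reference]:
    """Parse MEDLINE-style tagged text (PubMed export) into references.

    Indented continuation lines are joined to the preceding tag with a
    single space; a blank line separates records.
    """
    stream = _open_text(source)
    refs: list[Reference] = []
    raw: dict[str, list[str]] = {}
    last_tag: str | None = None
    record_index = 0

    def finish() -> None:
        nonlocal record_index, raw, last_tag
        if raw:
            try:
                refs.append(
                    _build_reference(
                        raw,
                        source_name,
                        record_index,
                        title_tags=("TI",),
                        abstract_tags=("AB",),
                        id_tags=("PMID",),
                        year_tags=("DP",),
                        author_tags=("FAU", "AU"),
                        source_tags=("JT", "TA"),
                    )
                )
            except ValueError as exc:
                err = RecordError(record_index, str(exc))
                if errors is not None:
                    errors.append(err)
                else:
                    warnings.warn(
                        f"MEDLINE record {record_index}: {exc}", stacklevel=2
                    )
            record_index += 1
        raw = {}
        last_tag = None

    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            finish()
            continue
        if line[0] in " \t" and last_tag is not None:
            raw[last_tag][-1] = f"{raw[last_tag][-1]} {line.strip()}"
            continue
        m = _MEDLINE_TAG.match(line)
        if m:
            tag, value = m.group(1), m.group(2)
            raw.setdefault(tag, []).append(value)
            last_tag = tag
    finish()
    return refs


def write_medline(refs: Iterable[Reference], stream: TextIO) -> None:
    """Serialise references to MEDLINE tagged text (no line re-wrapping)."""
    for ref in refs:
        raw = ref.raw or {"PMID": [ref.ref_id], "TI": [ref.title], "AB": [ref.abstract]}
        for tag, values in raw.items():
            for value in values:
                stream.write(f"{tag:<4}- {value}\n")
        stream.write("\n")


# --------------------------------------------------------------------------
# Cleaning
# --------------------------------------------------------------------------


def _doi(ref: Reference) -> str | None:
    for tag in ("DO", "DOI", "LID", "AID"):
        for value in ref.raw.get(tag, []):
            m = re.search(r"10\.\d{4,9}/\S+?(?=\s*\[|\s|$)", value)
            if m:
                return m.group(0).rstrip(".").casefold()
    return None


def deduplicate(
    refs: Sequence[Reference],
) -> tuple[list[Reference], list[Reference]]:
    """Remove duplicate records, keeping the first occurrence in order.

    Two records are duplicates when their titles match after casefolding,
    punctuation stripping and whitespace collapsing — and, if both carry a
    year, the years agree. A DOI shared by both records also forces a
    duplicate regardless of title.
    """
    kept: list[Reference] = []
    removed: list[Reference] = []
    by_title: dict[str, list[Reference]] = {}
    by_doi: dict[str, Reference] = {}
    for ref in refs:
        doi = _doi(ref)
        if doi is not None and doi in by_doi:
            removed.append(ref)
            continue
        key = _normalize_title(ref.title)
        dup = any(
            prev.year is None or ref.year is None or prev.year == ref.year
            for prev in by_title.get(key, [])
        )
        if dup:
            removed.append(ref)
            continue
        kept.append(ref)
        by_title.setdefault(key, []).append(ref)
        if doi is not None:
            by_doi[doi] = ref
    return kept, removed


def filter_has_abstract(
    refs: Sequence[Reference],
) -> tuple[list[Reference], list[Reference]]:
    """Partition references into (with abstract, without abstract)."""
    kept = [r for r in refs if r.has_abstract()]
    removed = [r for r in refs if not r.has_abstract()]
    return kept, removed


@dataclasses.dataclass
class CorpusBuildReport:
    """Accounting for the cleaning pipeline (nothing is silently dropped)."""

    corpus: Corpus
    duplicates_removed: list[Reference]
    no_abstract_removed: list[Reference]

    @property
    def n_after_dedup(self) -> int:
        return self.corpus.n_total - len(self.duplicates_removed)


def build_corpus(
    refs: Sequence[Reference], name: str
) -> CorpusBuildReport:
    """De-duplicate, drop abstract-less records, and assemble a Corpus."""
    deduped, dups = deduplicate(refs)
    with_abs, without_abs = filter_has_abstract(deduped)
    corpus = Corpus(
        name=name,
        references=with_abs,
        n_total=len(refs),
        n_with_abstract=len(with_abs),
    )
    return CorpusBuildReport(corpus, dups, without_abs)


def write_corpus_summary(
    reports: Iterable[CorpusBuildReport], stream: TextIO
) -> None:
    """Write the cleaning summary TSV (corpus, N, after-dedup, with-abstract)."""
    stream.write("corpus\tn_total\tn_after_dedup\tn_with_abstract\n")
    for rep in reports:
        stream.write(
            f"{rep.corpus.name}\t{rep.corpus.n_total}\t{rep.n_after_dedup}\t"
            f"{rep.corpus.n_with_abstract}\n"
        )


def read_gold_labels(
    source: str | Path | TextIO,
    review_name: str = "",
    corpus: Corpus | None = None,
) -> GoldLabels:
    """Load gold inclusion labels, one ref_id per line; ``#`` comments allowed.

    If *corpus* is given, every ID must belong to it.
    """
    stream = _open_text(source)
    ids = set()
    for line in stream:
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    gold = GoldLabels(included_ids=ids, review_name=review_name)
    if corpus is not None:
        gold.validate_against(corpus.ref_ids())
    return gold


def write_gold_labels(gold: GoldLabels, stream: TextIO) -> None:
    for ref_id in sorted(gold.included_ids):
        stream.write(f"{ref_id}\n")
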