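"""Detection of study-characteristic mentions in titles and abstracts.

The detector combines gazetteer longest-match over per-characteristic
lexicons with two shallow patterns tailored to observational-study
abstracts:

* population — a number followed within a short window by a person-class
  term ("1,234 children were enrolled");
* confounder — adjustment language ("adjusted for ...", "controlled for
  ...") followed by a noun phrase.

Downstream screening uses only the existential hit/miss flag per
characteristic; matched spans are retained for auditing. Span offsets are
0-based half-open character offsets into the field text, so every span
slices back to its surface form.
"""

from __future__ import annotations

import dataclasses
import enum
import re
from typing import Iterable, Sequence, TextIO

from .characteristics import CHARACTERISTIC_ORDER, Characteristic
from .lexicons import Lexicon, LexiconSet
from .reference_io import Reference


class Field(str, enum.Enum):
    TITLE = "title"
    ABSTRACT = "abstract"


class ExtractionError(ValueError):
    """Raised when a reference cannot be profiled (e.g. empty abstract)."""


@dataclasses.dataclass(frozen=True)
class Token:
    """One token with its character offsets into the source field text."""

    surface: str
    norm: str  # casefolded; "#NUM#" for numerals
    start: int
    end: int
    is_number: bool = False


@dataclasses.dataclass(frozen=True)
class TextSpan:
    """A matched characteristic mention."""

    ref_id: str
    field: Field
    start: int
    end: int
    surface: str
    phrase: str  # lexicon phrase or pattern name that fired
    characteristic: Characteristic


@dataclasses.dataclass
class CharacteristicProfile:
    """Hit/miss flags plus supporting spans for one reference."""

    ref_id: str
    hits: dict[Characteristic, bool]
    spans: list[TextSpan] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        # profiles loaded from a hits-only TSV carry no spans; the invariant
        # hits[c] <-> (>=1 span of c) is enforced whenever spans are recorded
        if not self.spans:
            return
        with_spans = {s.characteristic for s in self.spans}
        for c, hit in self.hits.items():
            if hit != (c in with_spans):
                raise ValueError(
                    f"profile {self.ref_id}: hits[{c.value}]={hit} "
                    f"inconsistent with spans"
                )

    @classmethod
    def from_spans(
        cls, ref_id: str, spans: Sequence[TextSpan]
    ) -> "CharacteristicProfile":
        with_spans = {s.characteristic for s in spans}
        return cls(
            ref_id,
            {c: c in with_spans for c in Characteristic},
            list(spans),
        )

    def hit_characteristics(self) -> frozenset[Characteristic]:
        return frozenset(c for c, h in self.hits.items() if h)


@dataclasses.dataclass(frozen=True)
class ExtractionConfig:
    """Extractor options.

    ``max_pattern_window`` caps, in tokens, how far the pattern rules look
    ahead from their trigger token.
    """

    match_title: bool = True
    enable_stemming: bool = False
    population_pattern: bool = True
    confounder_pattern: bool = True
    max_pattern_window: int = 5

    def __post_init__(self) -> None:
        if self.max_pattern_window < 1:
            raise ValueError("max_pattern_window must be >= 1")


DEFAULT_CONFIG = ExtractionConfig()

# Closed list of person-class terms for the population pattern.
PERSON_TERMS = frozenset(
    {
        "children", "women", "men", "adults", "participants", "subjects",
        "patients", "infants", "newborns", "neonates", "mothers", "adolescents",
        "individuals", "persons", "people", "workers", "residents", "births",
        "boys", "girls", "twins", "volunteers", "cases", "controls",
    }
)

# comma-grouped or plain numerals as single NUMBER tokens; words are letter runs,
# so hyphens and slashes split naturally
_TOKEN = re.compile(r"\d{1,3}(?:,\d{3})+(?:\.\d+)?|\d+(?:\.\d+)?|[^\W\d_]+")

_NUM_NORM = "#NUM#"


def stem(token: str) -> str:
    """Minimal deterministic suffix stripper used when stemming is enabled.

    Strips one of ``-ies/-ied → y``, ``-ing``, ``-ed``, ``-s`` (but not
    ``-ss``), keeping at least three characters of stem. Deliberately
    cruder than a full Porter stemmer: it only needs to conflate close
    inflectional variants — both the text token and the dictionary token
    pass through it, so the rule must be idempotent-ish, not linguistic.
    """
    if len(token) > 4 and token.endswith(("ies", "ied")):
        return token[:-3] + "y"
    for suffix in ("ing", "ed"):
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            return token[: -len(suffix)]
    if token.endswith("s") and not token.endswith("ss") and len(token) >= 4:
        return token[:-1]
    return token


def normalize_and_tokenize(text: str) -> list[Token]:
    """Casefolded tokens with offsets into the original string.

    Hyphens and slashes split tokens; numerals (including comma-grouped
    forms like "1,234") come through as single NUMBER tokens.
    """
    tokens = []
    for m in _TOKEN.finditer(text):
        surface = m.group(0)
        is_number = surface[0].isdigit()
        tokens.append(
            Token(
                surface=surface,
                norm=_NUM_NORM if is_number else surface.casefold(),
                start=m.start(),
                end=m.end(),
                is_number=is_number,
            )
        )
    return tokens


def _phrase_token_seqs(lexicon: Lexicon, stemmed: bool) -> dict[tuple[str, ...], str]:
    """Map phrase-token tuples (optionally stemmed) back to the lexicon phrase."""
    out: dict[tuple[str, ...], str] = {}
    for phrase in lexicon.phrases:
        toks = tuple(t.norm for t in normalize_and_tokenize(phrase))
        if not toks:
            continue
        if stemmed:
            toks = tuple(stem(t) for t in toks)
        out.setdefault(toks, phrase)
    return out


def match_lexicon(
    tokens: Sequence[Token],
    lexicon: Lexicon,
    config: ExtractionConfig = DEFAULT_CONFIG,
    *,
    ref_id: str = "",
    field: Field = Field.ABSTRACT,
    text: str = "",
) -> list[TextSpan]:
    """Longest-match, leftmost-first gazetteer matching.

    At each position the longest lexicon phrase that matches wins and the
    scan resumes after it, so overlapping shorter matches of the same
    characteristic are suppressed.
    """
    if not lexicon.phrases:
        return []
    seqs = _phrase_token_seqs(lexicon, config.enable_stemming)
    max_len = max(len(s) for s in seqs)
    norms = [
        stem(t.norm) if (config.enable_stemming and not t.is_number) else t.norm
        for t in tokens
    ]
    spans = []
    i = 0
    while i < len(tokens):
        matched = None
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            candidate = tuple(norms[i : i + length])
            if candidate in seqs:
                matched = (length, seqs[candidate])
                break
        if matched is None:
            i += 1
            continue
        length, phrase = matched
        start = tokens[i].start
        end = tokens[i + length - 1].end
        spans.append(
            TextSpan(
                ref_id=ref_id,
                field=field,
                start=start,
                end=end,
                surface=text[start:end] if text else phrase,
                phrase=phrase,
                characteristic=lexicon.characteristic,
            )
        )
        i += length
    return spans


POPULATION_PATTERN = "pattern:number-person"
CONFOUNDER_PATTERN = "pattern:adjust-for"

_ADJUST_STEMS = ("adjust", "controll")


def detect_population(
    tokens: Sequence[Token],
    lexicon: Lexicon,
    config: ExtractionConfig = DEFAULT_CONFIG,
    *,
    ref_id: str = "",
    field: Field = Field.ABSTRACT,
    text: str = "",
) -> list[TextSpan]:
    """Population mentions: lexicon matches plus the NUMBER + person pattern.

    The pattern fires when a NUMBER token is followed, within
    ``max_pattern_window`` tokens, by a person-class term from the built-in
    closed list.
    """
    spans = match_lexicon(
        tokens, lexicon, config, ref_id=ref_id, field=field, text=text
    )
    if not config.population_pattern:
        return spans
    for i, tok in enumerate(tokens):
        if not tok.is_number:
            continue
        window = tokens[i + 1 : i + 1 + config.max_pattern_window]
        for nxt in window:
            if nxt.norm in PERSON_TERMS:
                spans.append(
                    TextSpan(
                        ref_id=ref_id,
                        field=field,
                        start=tok.start,
                        end=nxt.end,
                        surface=text[tok.start : nxt.end]
                        if text
                        else f"{tok.surface} ... {nxt.surface}",
                        phrase=POPULATION_PATTERN,
                        characteristic=Characteristic.POPULATION,
                    )
                )
                break
    return spans


def detect_confounders(
    tokens: Sequence[Token],
    lexicon: Lexicon,
    config: ExtractionConfig = DEFAULT_CONFIG,
    *,
    ref_id: str = "",
    field: Field = Field.ABSTRACT,
    text: str = "",
) -> list[TextSpan]:
    """Confounder mentions: lexicon matches plus adjustment-language pattern.

    The pattern fires on a token stemming to "adjust"/"controll", followed
    by "for" and then at least one word token within
    ``max_pattern_window`` tokens (the adjusted-for noun phrase).
    """
    spans = match_lexicon(
        tokens, lexicon, config, ref_id=ref_id, field=field, text=text
    )
    if not config.confounder_pattern:
        return spans
    for i, tok in enumerate(tokens):
        if not tok.norm.startswith(_ADJUST_STEMS):
            continue
        if i + 1 >= len(tokens) or tokens[i + 1].norm != "for":
            continue
        window = tokens[i + 2 : i + 2 + config.max_pattern_window]
        for nxt in window:
            if not nxt.is_number:
                spans.append(
                    TextSpan(
                        ref_id=ref_id,
                        field=field,
                        start=tok.start,
                        end=nxt.end,
                        surface=text[tok.start : nxt.end]
                        if text
                        else f"{tok.surface} for {nxt.surface}",
                        phrase=CONFOUNDER_PATTERN,
                        characteristic=Characteristic.CONFOUNDER,
                    )
                )
                break
    return spans


def _detect_field(
    text: str,
    field: Field,
    ref_id: str,
    lexicons: LexiconSet,
    config: ExtractionConfig,
) -> list[TextSpan]:
    tokens = normalize_and_tokenize(text)
    spans: list[TextSpan] = []
    for c in Characteristic:
        kwargs = dict(ref_id=ref_id, field=field, text=text)
        if c is Characteristic.POPULATION:
            spans.extend(detect_population(tokens, lexicons[c], config, **kwargs))
        elif c is Characteristic.CONFOUNDER:
            spans.extend(detect_confounders(tokens, lexicons[c], config, **kwargs))
        else:
            spans.extend(match_lexicon(tokens, lexicons[c], config, **kwargs))
    return spans


def extract_characteristics(
    ref: Reference,
    lexicons: LexiconSet,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> CharacteristicProfile:
    """Profile one reference: run all detectors over title and abstract.

    References without abstracts must be filtered upstream; profiling one
    raises :class:`ExtractionError`.
    """
    if not ref.has_abstract():
        raise ExtractionError(
            f"reference {ref.ref_id} has no abstract; filter such records "
            "before extraction"
        )
    spans: list[TextSpan] = []
    if config.match_title:
        spans.extend(
            _detect_field(ref.title, Field.TITLE, ref.ref_id, lexicons, config)
        )
    spans.extend(
        _detect_field(ref.abstract, Field.ABSTRACT, ref.ref_id, lexicons, config)
    )
    return CharacteristicProfile.from_spans(ref.ref_id, spans)


def extract_corpus(
    refs: Iterable[Reference],
    lexicons: LexiconSet,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> list[CharacteristicProfile]:
    return [extract_characteristics(r, lexicons, config) for r in refs]


def write_profiles(
    profiles: Iterable[CharacteristicProfile], stream: TextIO
) -> None:
    """Profile TSV: ref_id then one 1/0 column per characteristic."""
    header = "\t".join(
        ["ref_id"] + [c.value for c in CHARACTERISTIC_ORDER]
    )
    stream.write(header + "\n")
    for p in profiles:
        row = [p.ref_id] + [
            "1" if p.hits[c] else "0" for c in CHARACTERISTIC_ORDER
        ]
        stream.write("\t".join(row) + "\n")


def read_profiles(source) -> list[CharacteristicProfile]:
    """Read a profile TSV written by :func:`write_profiles` (hits only)."""
    from .reference_io import _open_text

    stream = _open_text(source)
    header = next(stream).rstrip("\n").split("\t")
    cols = [Characteristic(name) for name in header[1:]]
    profiles = []
    for line in stream:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        hits = {c: v == "1" for c, v in zip(cols, parts[1:])}
        for c in Characteristic:
            hits.setdefault(c, False)
        profiles.append(CharacteristicProfile(parts[0], hits, spans=[]))
    return profiles


def write_spans(spans: Iterable[TextSpan], stream: TextIO) -> None:
    """Span TSV for auditing which phrase fired where."""
    stream.write(
        "ref_id\tcharacteristic\tfield\tstart\tend\tsurface\tphrase\n"
    )
    for s in spans:
        stream.write(
            f"{s.ref_id}\t{s.characteristic.value}\t{s.field.value}\t"
            f"{s.start}\t{s.end}\t{s.surface}\t{s.phrase}\n"
        )
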