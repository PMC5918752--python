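"""Per-characteristic term dictionaries (gazetteers).

A lexicon is a set of normalized multi-word phrases for one study
characteristic, loaded from a plain one-phrase-per-line text file so that
domain experts can audit and edit it. A :class:`LexiconSet` bundles exactly
one lexicon per characteristic; exposure and outcome lexicons are typically
swapped per review question, so lexicons carry provenance and support
merging.
"""

from __future__ import annotations

import dataclasses
import io
import re
import warnings
from pathlib import Path
from typing import Mapping, TextIO

import yaml

from .characteristics import CHARACTERISTIC_ORDER, Characteristic

_WS = re.compile(r"\s+")


class LexiconError(ValueError):
    """Invalid lexicon file or inconsistent lexicon operation."""


def normalize_phrase(phrase: str) -> str:
    """Casefold and collapse internal whitespace."""
    return _WS.sub(" ", phrase.casefold()).strip()


@dataclasses.dataclass(frozen=True)
class Lexicon:
    """An auditable set of normalized phrases for one characteristic."""

    characteristic: Characteristic
    phrases: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        for p in self.phrases:
            if not p or p != normalize_phrase(p):
                raise LexiconError(f"phrase not normalized or empty: {p!r}")

    def __len__(self) -> int:
        return len(self.phrases)

    def __contains__(self, phrase: str) -> bool:
        return normalize_phrase(phrase) in self.phrases

    @classmethod
    def empty(cls, characteristic: Characteristic) -> "Lexicon":
        """Explicitly construct an empty lexicon (never created by accident)."""
        return cls(characteristic, frozenset(), provenance="empty")

    @classmethod
    def from_phrases(
        cls,
        characteristic: Characteristic,
        phrases,
        provenance: str = "",
    ) -> "Lexicon":
        return cls(
            characteristic,
            frozenset(normalize_phrase(p) for p in phrases if p.strip()),
            provenance,
        )


def load_lexicon(
    source: str | Path | TextIO,
    characteristic: Characteristic,
    provenance: str | None = None,
) -> Lexicon:
    """Load a lexicon from a one-phrase-per-line file.

    Lines starting with ``#`` are comments. Phrases are casefolded and
    whitespace-collapsed; duplicates after normalization are collapsed with
    a warning giving the count. A file empty after comment removal is an
    error — empty lexicons must be built via :meth:`Lexicon.empty`.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        stream: TextIO = io.StringIO(path.read_text("utf-8"))
        if provenance is None:
            provenance = path.name
    else:
        stream = source
        if provenance is None:
            provenance = "<stream>"
    raw = [
        line.strip()
        for line in stream
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not raw:
        raise LexiconError(
            f"lexicon source {provenance!r} holds no phrases; use "
            "Lexicon.empty() to create an empty lexicon deliberately"
        )
    normalized = [normalize_phrase(p) for p in raw]
    phrases = frozenset(normalized)
    n_dupes = len(normalized) - len(phrases)
    if n_dupes:
        warnings.warn(
            f"lexicon {provenance!r}: collapsed {n_dupes} duplicate "
            f"phrase(s) after normalization",
            stacklevel=2,
        )
    return Lexicon(characteristic, phrases, provenance)


def merge_lexicons(a: Lexicon, b: Lexicon) -> Lexicon:
    """Union of two lexicons for the same characteristic."""
    if a.characteristic is not b.characteristic:
        raise LexiconError(
            f"cannot merge {a.characteristic.value} lexicon with "
            f"{b.characteristic.value} lexicon"
        )
    provenance = "+".join(p for p in (a.provenance, b.provenance) if p)
    return Lexicon(a.characteristic, a.phrases | b.phrases, provenance)


class LexiconSet(Mapping[Characteristic, Lexicon]):
    """Exactly one lexicon per characteristic (any may be empty)."""

    def __init__(self, lexicons: Mapping[Characteristic, Lexicon]):
        missing = set(Characteristic) - set(lexicons)
        extra = set(lexicons) - set(Characteristic)
        if missing or extra:
            raise LexiconError(
                f"LexiconSet needs exactly the six characteristics; "
                f"missing={sorted(c.value for c in missing)} "
                f"extra={sorted(getattr(c, 'value', c) for c in extra)}"
            )
        for c, lex in lexicons.items():
            if lex.characteristic is not c:
                raise LexiconError(
                    f"lexicon for key {c.value} is labelled "
                    f"{lex.characteristic.value}"
                )
        self._lexicons = dict(lexicons)

    def __getitem__(self, key: Characteristic) -> Lexicon:
        return self._lexicons[key]

    def __iter__(self):
        return iter(CHARACTERISTIC_ORDER)

    def __len__(self) -> int:
        return len(self._lexicons)

    def with_lexicon(self, lexicon: Lexicon) -> "LexiconSet":
        """A copy with one characteristic's lexicon replaced."""
        updated = dict(self._lexicons)
        updated[lexicon.characteristic] = lexicon
        return LexiconSet(updated)

    def merged_with(self, other: "LexiconSet") -> "LexiconSet":
        return LexiconSet(
            {c: merge_lexicons(self[c], other[c]) for c in Characteristic}
        )

    @classmethod
    def all_empty(cls) -> "LexiconSet":
        return cls({c: Lexicon.empty(c) for c in Characteristic})

    @classmethod
    def from_phrase_map(
        cls, phrase_map: Mapping[Characteristic, list[str] | tuple[str, ...]],
        provenance: str = "",
    ) -> "LexiconSet":
        """Build a set from in-memory phrase lists; absent keys are empty."""
        lexicons = {}
        for c in Characteristic:
            phrases = phrase_map.get(c)
            lexicons[c] = (
                Lexicon.from_phrases(c, phrases, provenance)
                if phrases
                else Lexicon.empty(c)
            )
        return cls(lexicons)

    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "LexiconSet":
        """Load a set from a YAML manifest mapping characteristic → path.

        All six characteristics must appear as keys; a null value declares
        that characteristic's lexicon deliberately empty. Relative paths are
        resolved against the manifest's directory.
        """
        manifest_path = Path(manifest_path)
        doc = yaml.safe_load(manifest_path.read_text("utf-8"))
        if not isinstance(doc, dict):
            raise LexiconError(f"manifest {manifest_path} is not a mapping")
        entries: dict[Characteristic, Lexicon] = {}
        for key, value in doc.items():
            c = Characteristic.from_name(str(key))
            if c in entries:
                raise LexiconError(f"manifest lists {c.value} twice")
            if value is None:
                entries[c] = Lexicon.empty(c)
            else:
                path = Path(value)
                if not path.is_absolute():
                    path = manifest_path.parent / path
                entries[c] = load_lexicon(path, c)
        return cls(entries)  # completeness checked by the constructor
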