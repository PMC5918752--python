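"""Threshold screening rules over characteristic profiles.

A rule is a pair (S, k): include a reference when at least k of the
characteristics in S were hit. Rules are restricted to the PECO subset —
country and study type are extracted for audit but never screened on,
because only PECO elements define relevance to a review question. Six
named built-ins cover the spectrum from strictest (all four PECO
elements) to the exposure+outcome pair:

==========  =============  ==
name        S              k
==========  =============  ==
All4        {P, E, C, O}   4
Any3        {P, E, C, O}   3
Any2        {P, E, C, O}   2
PEO         {P, E, O}      3
PE          {P, E}         2
EO          {E, O}         2
==========  =============  ==
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Sequence, TextIO

from .characteristics import PECO, Characteristic
from .extractor import CharacteristicProfile

P = Characteristic.POPULATION
E = Characteristic.EXPOSURE
C = Characteristic.CONFOUNDER
O = Characteristic.OUTCOME


class Verdict(str, enum.Enum):
    INCLUDE = "include"
    EXCLUDE = "exclude"


@dataclasses.dataclass(frozen=True)
class ScreeningRule:
    """Include a reference iff >= ``min_hits`` of ``char_set`` were hit."""

    name: str
    char_set: frozenset[Characteristic]
    min_hits: int

    def __post_init__(self) -> None:
        if not self.char_set:
            raise ValueError("rule characteristic set must be non-empty")
        if not self.char_set <= PECO:
            bad = sorted(c.value for c in self.char_set - PECO)
            raise ValueError(
                f"screening rules are limited to PECO characteristics; "
                f"got {bad}"
            )
        if not 1 <= self.min_hits <= len(self.char_set):
            raise ValueError(
                f"min_hits must be in [1, {len(self.char_set)}], "
                f"got {self.min_hits}"
            )


BUILT_IN_RULES: dict[str, ScreeningRule] = {
    r.name: r
    for r in (
        ScreeningRule("All4", frozenset({P, E, C, O}), 4),
        ScreeningRule("Any3", frozenset({P, E, C, O}), 3),
        ScreeningRule("Any2", frozenset({P, E, C, O}), 2),
        ScreeningRule("PEO", frozenset({P, E, O}), 3),
        ScreeningRule("PE", frozenset({P, E}), 2),
        ScreeningRule("EO", frozenset({E, O}), 2),
    )
}


def parse_rule(spec: str) -> ScreeningRule:
    """Resolve a built-in rule name or a ``custom:P,E,O:2`` spec string."""
    if spec in BUILT_IN_RULES:
        return BUILT_IN_RULES[spec]
    if spec.startswith("custom:"):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(
                f"custom rule spec must look like 'custom:P,E,O:2', got {spec!r}"
            )
        chars = frozenset(
            Characteristic.from_name(tok) for tok in parts[1].split(",") if tok
        )
        try:
            k = int(parts[2])
        except ValueError:
            raise ValueError(f"custom rule threshold not an integer: {parts[2]!r}")
        return ScreeningRule(spec, chars, k)
    raise ValueError(
        f"unknown rule {spec!r}; valid names: {', '.join(BUILT_IN_RULES)} "
        "or 'custom:P,E,O:2' syntax"
    )


@dataclasses.dataclass(frozen=True)
class Decision:
    """The screening verdict for one reference under one rule."""

    ref_id: str
    rule_name: str
    verdict: Verdict
    n_hits_in_set: int


def apply_rule(
    profile: CharacteristicProfile, rule: ScreeningRule
) -> Decision:
    """Pure threshold test: count hits within the rule's characteristic set."""
    n_hits = sum(1 for c in rule.char_set if profile.hits.get(c, False))
    verdict = Verdict.INCLUDE if n_hits >= rule.min_hits else Verdict.EXCLUDE
    return Decision(profile.ref_id, rule.name, verdict, n_hits)


def screen_corpus(
    profiles: Sequence[CharacteristicProfile], rule: ScreeningRule
) -> tuple[set[str], set[str]]:
    """Partition profile ref_ids into (included, excluded) under one rule."""
    seen: set[str] = set()
    included: set[str] = set()
    excluded: set[str] = set()
    for p in profiles:
        if p.ref_id in seen:
            raise ValueError(f"duplicate ref_id among profiles: {p.ref_id}")
        seen.add(p.ref_id)
        d = apply_rule(p, rule)
        (included if d.verdict is Verdict.INCLUDE else excluded).add(p.ref_id)
    return included, excluded


def write_decisions(
    profiles: Iterable[CharacteristicProfile],
    rules: Sequence[ScreeningRule],
    stream: TextIO,
) -> None:
    """Decisions TSV: one row per (reference, rule)."""
    stream.write("ref_id\trule\tverdict\tn_hits\n")
    for p in profiles:
        for rule in rules:
            d = apply_rule(p, rule)
            stream.write(
                f"{d.ref_id}\t{d.rule_name}\t{d.verdict.value}\t"
                f"{d.n_hits_in_set}\n"
            )
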