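"""The six study characteristics of observational epidemiological studies.

Population, Exposure, Confounder and Outcome (collectively PECO — the
observational analogue of PICO) drive screening decisions; country and
study type are extracted but never screened on.
"""

from __future__ import annotations

import enum


class Characteristic(str, enum.Enum):
    """One of the six study characteristics detectable in a title/abstract."""

    POPULATION = "population"
    EXPOSURE = "exposure"
    CONFOUNDER = "confounder"
    OUTCOME = "outcome"
    COUNTRY = "country"
    STUDY_TYPE = "study_type"

    @property
    def letter(self) -> str:
        """Single-letter PECO abbreviation (P/E/C/O); two letters otherwise."""
        return _LETTERS[self]

    @classmethod
    def from_name(cls, name: str) -> "Characteristic":
        """Resolve a characteristic from its full name or letter code."""
        key = name.strip().lower()
        for c in cls:
            if key in (c.value, c.letter.lower()):
                return c
        raise ValueError(
            f"unknown characteristic {name!r}; expected one of "
            f"{[c.value for c in cls]} or letters {[c.letter for c in cls]}"
        )


_LETTERS = {
    Characteristic.POPULATION: "P",
    Characteristic.EXPOSURE: "E",
    Characteristic.CONFOUNDER: "C",
    Characteristic.OUTCOME: "O",
    Characteristic.COUNTRY: "CY",
    Characteristic.STUDY_TYPE: "ST",
}

#: The four characteristics screening rules may test.
PECO = frozenset(
    {
        Characteristic.POPULATION,
        Characteristic.EXPOSURE,
        Characteristic.CONFOUNDER,
        Characteristic.OUTCOME,
    }
)

#: Canonical display order used in reports and TSV columns.
CHARACTERISTIC_ORDER = (
    Characteristic.POPULATION,
    Characteristic.EXPOSURE,
    Characteristic.CONFOUNDER,
    Characteristic.OUTCOME,
    Characteristic.COUNTRY,
    Characteristic.STUDY_TYPE,
)
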