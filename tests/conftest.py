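import io

import pytest
from hypothesis import HealthCheck, settings

from pecoscreen.characteristics import Characteristic
from pecoscreen.lexicons import Lexicon, LexiconSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


RIS_FIXTURE = """\
TY  - JOUR
TI  - Serum PFOA and birth weight in a prospective cohort
AU  - Example, A.
PY  - 2012
AB  - We measured serum PFOA in 1,234 pregnant women and recorded birth weight.
ER  -
TY  - JOUR
TI  - Particulate matter and lung cancer mortality
AU  - Example, B.
AU  - Example, C.
PY  - 2010
AB  - Cohort study of air pollution, adjusted for smoking and age.
ER  -
TY  - JOUR
TI  - A record with no abstract at all
PY  - 2011
ER  -
"""

MEDLINE_FIXTURE = """\
PMID- 100001
TI  - Serum PFOA and birth weight in a prospective
      cohort of pregnant women
AB  - We measured serum PFOA in pregnant women and
      recorded birth weight at delivery.
DP  - 2012 Mar
AU  - Example A

PMID- 100002
TI  - Particulate matter and lung cancer
AB  - Cohort study of air pollution and lung cancer, adjusted for smoking.
DP  - 2010

PMID- 100003
TI  - A record lacking an abstract
DP  - 2011
"""


@pytest.fixture
def ris_stream():
    return io.StringIO(RIS_FIXTURE)


@pytest.fixture
def medline_stream():
    return io.StringIO(MEDLINE_FIXTURE)


@pytest.fixture
def pfoa_lexicons() -> LexiconSet:
    """Small in-memory lexicon set for the PFOA / fetal-growth topic."""
    return LexiconSet.from_phrase_map(
        {
            Characteristic.POPULATION: ["pregnant women", "infants"],
            Characteristic.EXPOSURE: ["pfoa", "pfos", "perfluorooctanoic acid"],
            Characteristic.CONFOUNDER: ["maternal age", "smoking"],
            Characteristic.OUTCOME: ["birth weight", "fetal growth"],
            Characteristic.COUNTRY: ["denmark"],
            Characteristic.STUDY_TYPE: ["cohort study"],
        },
        provenance="test fixture",
    )


@pytest.fixture
def empty_lexicons() -> LexiconSet:
    return LexiconSet.all_empty()


def make_lexicon(characteristic, phrases):
    return Lexicon.from_phrases(characteristic, phrases, provenance="test")
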