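"""Screen a small reference export by detected study characteristics.

Builds a four-record RIS export in memory, profiles each abstract against
the shipped PFOA/fetal-growth lexicons, and applies the exposure+outcome
(EO) threshold rule. The printed verdicts show why the rule works: records
whose abstracts name both the exposure and the outcome are kept for human
review, the rest are screened out.
"""

import io
from importlib import resources

from pecoscreen import (
    BUILT_IN_RULES,
    LexiconSet,
    apply_rule,
    extract_corpus,
    read_ris,
)

RIS = """\
TY  - JOUR
TI  - Serum PFOA and birth weight in a prospective cohort
AB  - We measured serum PFOA in pregnant women and recorded birth weight.
ER  -
TY  - JOUR
TI  - Dietary patterns of urban adolescents
AB  - A food-frequency survey of adolescents; no chemical exposures assessed.
ER  -
TY  - JOUR
TI  - PFOS exposure and fetal growth in a birth cohort
AB  - Cord serum PFOS was associated with fetal growth, adjusted for smoking.
ER  -
TY  - JOUR
TI  - PFC levels in maternal cord blood
AB  - PFC concentrations in maternal cord blood samples were quantified.
ER  -
"""

manifest = resources.files("pecoscreen").joinpath(
    "data/lexicons/pfoa_fetal_growth.yaml"
)
lexicons = LexiconSet.from_manifest(str(manifest))
references = read_ris(io.StringIO(RIS), source_name="demo")
profiles = extract_corpus(references, lexicons)

rule = BUILT_IN_RULES["EO"]
print(f"rule {rule.name}: include iff >= {rule.min_hits} of "
      f"{sorted(c.value for c in rule.char_set)} are hit\n")
for ref, profile in zip(references, profiles):
    decision = apply_rule(profile, rule)
    hit = ",".join(sorted(c.letter for c, h in profile.hits.items() if h))
    print(f"{decision.verdict.value:>8}  hits=[{hit:<12}]  {ref.title}")

print(
    "\nThe last record mentions its exposure only as 'PFC' — a synonym the"
    "\ndictionary does not know — so it is screened out: the dictionary-"
    "\ncoverage failure mode that causes false negatives in practice."
)
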