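# Population terms for observational environmental-health studies
pregnant women
pregnant mothers
infants
newborns
neonates
children
school-age children
adolescents
adults
elderly adults
general population
workers
mother-child pairs
birth cohort
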