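# Lexicon manifest for a PFOA / fetal-growth review question.
# All six characteristics must be listed; a null value declares the
# lexicon deliberately empty.
population: population.txt
exposure: exposure_pfoa.txt
confounder: confounder.txt
outcome: outcome_birthweight.txt
country: country.txt
study_type: study_type.txt
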