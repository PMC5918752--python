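# Common adjustment variables in environmental epidemiology
smoking
maternal age
socioeconomic status
alcohol consumption
education
gestational age
pre-pregnancy bmi
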