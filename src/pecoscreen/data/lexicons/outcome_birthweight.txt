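# Outcome terms: fetal growth
birth weight
low birth weight
fetal growth
birth length
head circumference
small for gestational age
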