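# Exposure terms: bisphenol A (obesity review topic)
bisphenol a
bpa
urinary bpa
bisphenol a glucuronide
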