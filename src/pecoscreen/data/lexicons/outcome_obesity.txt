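# Outcome terms: obesity
obesity
overweight
body mass index
adiposity
waist circumference
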