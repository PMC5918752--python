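# Outcome terms: lung cancer
lung cancer
lung carcinoma
lung cancer incidence
lung cancer mortality
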