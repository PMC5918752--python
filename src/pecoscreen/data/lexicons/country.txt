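# Country mentions
united states
denmark
norway
sweden
japan
china
canada
united kingdom
australia
netherlands
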