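# Exposure terms: perfluorinated compounds (fetal-growth review topic)
pfoa
pfos
perfluorooctanoic acid
perfluorooctane sulfonate
perfluorooctane sulfonic acid
perfluoroalkyl substances
perfluoroalkyl acids
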