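# Study-design phrases
cohort study
prospective cohort
retrospective cohort
case-control study
cross-sectional study
longitudinal study
nested case-control
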