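# Exposure terms: outdoor particulate matter (lung-cancer review topic)
particulate matter
fine particulate matter
pm2.5
pm10
air pollution
ambient air pollution
traffic-related air pollution
black carbon
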