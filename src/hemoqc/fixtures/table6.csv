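characteristic,category,count,percent
bmi,low,39,24.4
bmi,normal,174,34.5
bmi,high,57,41.1
serum_calcium,low,12,14.6
serum_calcium,normal,187,49.2
serum_calcium,high,71,36.2
hematocrit,low,18,6.5
hematocrit,normal,54,20.1
hematocrit,high,198,73.4
ferritin,low,65,23.9
ferritin,normal,178,65.9
ferritin,high,27,10.2
transferrin_saturation,low,48,27.8
transferrin_saturation,normal,222,72.2
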