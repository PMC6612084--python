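combination,anticoagulation,blood_flow,dehydration,vascular_access,defective,good,total
A1B3C2D2,500 units,300 ml/min,2.5 kg,autologous blood vessel,35,235,270
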