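characteristic,category,count,percent
residence,downtown,95,35.1
residence,rural area,150,55.6
residence,fishing village,25,9.3
gender,male,127,46.9
gender,female,143,53.1
age,<50,48,17.9
age,51-64,90,33.2
age,65-74,56,20.6
age,>=75,76,28.3
primary_disease,chronic glomerulonephritis,168,62.1
primary_disease,diabetes,100,36.9
primary_disease,others,2,1.0
unstable_blood_pressure,yes,111,41.1
unstable_blood_pressure,no,159,58.9
blurred_vision,yes,76,28.3
blurred_vision,no,194,71.7
physical_disorder,yes,37,13.7
physical_disorder,no,233,86.3
unconsciousness,yes,5,1.9
unconsciousness,no,265,98.1
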