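factor,label,level,value,unit
A,Amount of anticoagulation,1,500,units
A,Amount of anticoagulation,2,1000,units
A,Amount of anticoagulation,3,1500,units
B,Velocity of blood flow,1,200,ml/min
B,Velocity of blood flow,2,250,ml/min
B,Velocity of blood flow,3,300,ml/min
C,Dehydration volume,1,1.5,kg
C,Dehydration volume,2,2.5,kg
C,Dehydration volume,3,3.5,kg
D,Vascular access type,1,artificial blood vessel,
D,Vascular access type,2,autologous blood vessel,
D,Vascular access type,3,temporary duct,
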