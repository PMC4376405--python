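formulation,ingredient,percentage
A,peanuts,38.4
A,cowpeas,22.2
A,millet,18.4
A,sugar,14.0
A,rice,7.0
B,peanuts,39.0
B,cowpeas,21.8
B,millet,11.2
B,sugar,14.0
B,rice,14.0
C,peanuts,39.5
C,cowpeas,21.4
C,millet,4.1
C,sugar,14.0
C,rice,21.0
D,peanuts,38.2
D,cowpeas,21.9
D,millet,20.9
D,sugar,14.0
D,barley,5.0
E,peanuts,38.5
E,cowpeas,21.2
E,millet,16.3
E,sugar,14.0
E,barley,10.0
F,peanuts,38.8
F,cowpeas,20.5
F,millet,11.8
F,sugar,14.0
F,barley,15.0
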