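ingredient,year,price_usd_per_kg
barley,2004,0.19
barley,2005,0.19
barley,2006,0.19
barley,2007,0.22
barley,2008,0.23
barley,2009,0.34
cassava,2004,0.38
cassava,2005,0.38
cassava,2006,0.38
cassava,2007,0.11
cassava,2008,0.09
cassava,2009,0.06
corn,2004,0.10
corn,2005,0.20
corn,2006,0.17
corn,2007,0.15
corn,2008,0.17
corn,2009,0.18
cowpeas,2004,0.26
cowpeas,2005,0.26
cowpeas,2006,0.26
cowpeas,2007,0.30
cowpeas,2008,0.36
cowpeas,2009,0.35
fonio,2004,0.56
fonio,2005,0.56
fonio,2006,0.57
fonio,2007,0.63
fonio,2008,0.83
fonio,2009,0.83
millet,2004,0.12
millet,2005,0.25
millet,2006,0.20
millet,2007,0.18
millet,2008,0.19
millet,2009,0.29
peanuts,2004,0.24
peanuts,2005,0.24
peanuts,2006,0.31
peanuts,2007,0.40
peanuts,2008,0.47
peanuts,2009,0.51
rice,2004,0.21
rice,2005,0.27
rice,2006,0.25
rice,2007,0.25
rice,2008,0.26
rice,2009,0.32
sorghum,2004,0.11
sorghum,2005,0.23
sorghum,2006,0.18
sorghum,2007,0.18
sorghum,2008,0.19
sorghum,2009,0.24
sugar,2004,1.03
sugar,2005,1.03
sugar,2006,1.03
sugar,2007,1.03
sugar,2008,1.03
sugar,2009,1.03
yam,2004,0.34
yam,2005,0.63
yam,2006,0.63
yam,2007,0.31
yam,2008,0.28
yam,2009,0.23
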