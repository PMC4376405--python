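name,basis,protein_pct,fat_pct,ash_pct,fiber_pct,carbohydrate_pct,energy_kcal,moisture_pct,lys,leu,val,his,trp,thr,ile,met,cys,phe,tyr,notes
peanuts,dry,24.0,47.9134,1.8,9.0213,17.2653,557.8,0.0,0.5226,1.3137,0.8819,0.3997,0.138,0.5797,0.537,0.18,0.3969,1.6701,0.8378,"blanched, roasted; reference approximation"
cowpeas,dry,24.7317,2.4983,4.2607,9.0,59.5093,330.0,0.0,2.2755,2.632,1.638,1.064,0.4156,1.2155,1.4,0.4835,0.162,0.852,1.12,decorticated; reference approximation
millet,dry,12.4941,4.9811,3.1399,9.1696,70.2153,400.55,0.0,0.2263,1.2064,0.408,0.3258,0.1651,0.5125,0.6219,0.2909,0.2013,0.5547,0.357,flour; reference approximation
sugar,dry,0.01,0.01,0.0,0.0,99.98,380.0,0.0,0.0006,0.0003,0.0007,0.0007,0.0007,0.0007,0.0007,0.0007,0.0003,0.0003,0.0007,granulated; reference approximation
rice,dry,8.5,1.499,0.5568,0.5,88.9442,382.49,0.0,0.32,0.42,0.3081,0.28,0.14,0.434,0.4876,0.2485,0.102,0.27,0.2406,"white, for koji; unfermented grain profile; reference approximation"
barley,dry,11.697,1.96,1.2,15.9041,69.2389,369.58,0.0,0.4934,0.5908,0.4339,0.3366,0.2574,0.56,0.588,0.308,0.1968,0.4241,0.204,"pearled, for koji; unfermented grain profile; reference approximation"
corn,dry,10.5,5.3,1.6,8.1,74.5,408,0.0,0.3,1.36,0.53,0.32,0.08,0.4,0.4,0.22,0.21,0.55,0.45,grain; reference approximation
sorghum,dry,12.4,3.8,1.7,7.0,75.1,405,0.0,0.26,1.55,0.58,0.27,0.13,0.38,0.48,0.19,0.2,0.61,0.37,grain; reference approximation
fonio,dry,9.0,2.0,1.3,3.6,84.1,398,0.0,0.22,0.95,0.5,0.2,0.15,0.33,0.38,0.4,0.23,0.52,0.32,grain; reference approximation
cassava,dry,3.5,0.7,1.6,4.6,89.6,395,0.0,0.15,0.14,0.12,0.07,0.06,0.1,0.1,0.04,0.07,0.1,0.06,"root, dried; reference approximation"
yam,dry,6.5,0.6,3.4,4.7,84.8,390,0.0,0.27,0.45,0.29,0.14,0.08,0.23,0.25,0.1,0.09,0.31,0.18,"tuber, dried; reference approximation"
sesame,dry,18.7,52.2,4.8,12.4,11.9,601,0.0,0.57,1.42,1.04,0.55,0.41,0.77,0.8,0.61,0.38,0.99,0.78,seed; reference approximation
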