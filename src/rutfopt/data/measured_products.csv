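product,nutrient,predicted,actual,reported_difference
A,protein,17.6,19.5,1.86
A,fat,20.0,19.3,-0.68
A,ash,2.25,2.95,0.7
A,fiber,7.18,6.9,-0.28
A,carbohydrate,52.5,51.3,-1.13
A,energy,441,457,16.0
A,lys,0.77,0.59,-0.17
A,leu,1.34,1.42,0.08
A,val,0.8,0.82,0.02
A,his,0.47,0.41,-0.06
A,trp,0.19,0.2,0.01
A,thr,0.62,0.58,-0.04
A,ile,0.67,0.71,0.05
A,met,0.25,0.27,0.02
A,cys,0.23,0.21,-0.03
A,met_cys,0.48,0.47,-0.01
A,phe,0.95,1.0,0.05
A,tyr,0.65,0.76,0.11
A,phe_tyr,1.6,1.76,0.16
B,protein,17.3,19.3,1.95
B,fat,20.0,19.1,-0.88
B,ash,2.06,2.81,0.75
B,fiber,6.58,6.42,-0.16
B,carbohydrate,52.7,52.4,-0.32
B,energy,441,459,17.5
B,lys,0.77,0.57,-0.2
B,leu,1.28,1.34,0.06
B,val,0.79,0.79,0.01
B,his,0.46,0.4,-0.06
B,trp,0.18,0.19,0.0
B,thr,0.61,0.58,-0.03
B,ile,0.65,0.69,0.03
B,met,0.24,0.26,0.02
B,cys,0.23,0.2,-0.03
B,met_cys,0.47,0.46,-0.01
B,phe,0.94,0.98,0.04
B,tyr,0.64,0.74,0.1
B,phe_tyr,1.58,1.72,0.14
C,protein,17.1,18.5,1.45
C,fat,20.0,19.2,-0.86
C,ash,1.87,2.76,0.89
C,fiber,5.97,6.46,0.49
C,carbohydrate,52.9,53.1,0.25
C,energy,441,459,17.7
C,lys,0.77,0.52,-0.25
C,leu,1.22,1.25,0.03
C,val,0.78,0.77,-0.01
C,his,0.46,0.39,-0.07
C,trp,0.18,0.18,-0.01
C,thr,0.6,0.55,-0.05
C,ile,0.64,0.67,0.02
C,met,0.24,0.25,0.01
C,cys,0.22,0.19,-0.03
C,met_cys,0.46,0.44,-0.03
C,phe,0.92,0.94,0.02
C,tyr,0.64,0.72,0.08
C,phe_tyr,1.56,1.65,0.1
D,protein,17.8,19.8,2.04
D,fat,20.0,19.8,-0.19
D,ash,2.34,2.94,0.6
D,fiber,8.13,6.07,-2.06
D,carbohydrate,52.4,51.3,-1.1
D,energy,441,463,22.2
D,lys,0.77,0.56,-0.21
D,leu,1.36,1.45,0.09
D,val,0.8,0.83,0.03
D,his,0.47,0.42,-0.05
D,trp,0.19,0.19,0.0
D,thr,0.62,0.58,-0.04
D,ile,0.67,0.72,0.05
D,met,0.25,0.28,0.03
D,cys,0.24,0.21,-0.03
D,met_cys,0.49,0.49,0.0
D,phe,0.96,1.02,0.06
D,tyr,0.65,0.76,0.11
D,phe_tyr,1.61,1.78,0.17
E,protein,17.7,19.6,1.92
E,fat,20.0,19.8,-0.18
E,ash,2.23,2.91,0.68
E,fiber,8.47,7.16,-1.31
E,carbohydrate,52.6,50.5,-2.12
E,energy,440,459,18.4
E,lys,0.77,0.54,-0.22
E,leu,1.32,1.39,0.07
E,val,0.8,0.8,0.0
E,his,0.47,0.4,-0.07
E,trp,0.19,0.19,0.0
E,thr,0.62,0.57,-0.05
E,ile,0.66,0.71,0.04
E,met,0.25,0.26,0.01
E,cys,0.24,0.21,-0.03
E,met_cys,0.49,0.47,-0.02
E,phe,0.96,1.0,0.04
E,tyr,0.65,0.74,0.09
E,phe_tyr,1.61,1.73,0.13
F,protein,17.6,19.6,1.99
F,fat,20.0,19.6,-0.43
F,ash,2.12,2.89,0.77
F,fiber,8.81,7.89,-0.92
F,carbohydrate,52.8,50.1,-2.72
F,energy,440,455,14.8
F,lys,0.77,0.52,-0.25
F,leu,1.28,1.35,0.07
F,val,0.79,0.8,0.01
F,his,0.46,0.39,-0.07
F,trp,0.2,0.18,-0.01
F,thr,0.62,0.57,-0.05
F,ile,0.66,0.69,0.04
F,met,0.25,0.26,0.01
F,cys,0.24,0.21,-0.03
F,met_cys,0.49,0.47,-0.02
F,phe,0.95,0.99,0.04
F,tyr,0.62,0.74,0.1
F,phe_tyr,,1.73,0.13
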