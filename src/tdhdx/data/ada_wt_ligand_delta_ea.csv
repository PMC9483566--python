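peptide_id,pair,delta,sigma,indeterminate
46-62,ES-apo,3.15,2.0,0
46-62,ETS-apo,6.01,2.0,0
46-62,ETS-ES,2.86,1.8,0
86-97,ES-apo,2.42,2.2,0
86-97,ETS-apo,4.76,2.3,0
86-97,ETS-ES,2.34,0.9,0
109-131,ES-apo,2.35,2.0,0
109-131,ETS-apo,2.61,2.2,0
109-131,ETS-ES,0.26,1.0,0
132-144,ES-apo,8.24,1.9,0
132-144,ETS-apo,8.88,2.6,0
132-144,ETS-ES,0.64,1.8,0
155-163,ES-apo,6.07,2.9,0
155-163,ETS-apo,4.59,4.2,0
155-163,ETS-ES,-1.48,5.1,0
180-200,ES-apo,4.73,3.1,0
180-200,ETS-apo,5.15,3.0,0
180-200,ETS-ES,0.42,4.1,0
201-229,ES-apo,-6.46,1.6,0
201-229,ETS-apo,-9.3,1.5,0
201-229,ETS-ES,-2.84,1.3,0
230-248,ES-apo,1.97,1.0,0
230-248,ETS-apo,2.45,1.9,0
230-248,ETS-ES,0.48,1.8,0
253-259,ES-apo,4.77,1.5,0
253-259,ETS-apo,4.59,2.6,0
253-259,ETS-ES,-0.18,2.5,0
301-320,ES-apo,11.2,2.3,0
301-320,ETS-apo,11.7,2.1,0
301-320,ETS-ES,0.5,3.0,0
348-352,ES-apo,6.63,1.5,0
348-352,ETS-apo,5.77,1.7,0
348-352,ETS-ES,-0.86,1.4,0
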