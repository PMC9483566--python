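peptide_id,pair,delta,sigma,indeterminate
15-28,F61A-WT-apo,-7.6,1.4,0
15-28,F61A-WT-ETS,0.3,3.1,1
46-62,F61A-WT-apo,-4.8,2.1,0
46-62,F61A-WT-ETS,-9.05,2.9,0
63-74,F61A-WT-apo,-6.1,2.4,0
63-74,F61A-WT-ETS,-2.48,5.7,1
86-97,F61A-WT-apo,-1.4,2.7,1
86-97,F61A-WT-ETS,-4.5,1.9,0
155-163,F61A-WT-apo,-3.3,0.9,0
155-163,F61A-WT-ETS,-4.54,6.8,1
167-179,F61A-WT-apo,-2,1.3,0
167-179,F61A-WT-ETS,1.67,1.8,1
180-200,F61A-WT-apo,-3.1,1.5,0
180-200,F61A-WT-ETS,-1.77,3.4,1
201-229,F61A-WT-apo,-6.2,1.6,0
201-229,F61A-WT-ETS,-2.55,1.7,0
230-248,F61A-WT-apo,-3.3,1.0,0
230-248,F61A-WT-ETS,-5.34,3.3,0
260-267,F61A-WT-apo,-3.1,3.4,0
260-267,F61A-WT-ETS,-4.83,2.8,0
268-290,F61A-WT-apo,-5.1,2.1,0
268-290,F61A-WT-ETS,-5.46,2.6,0
301-320,F61A-WT-apo,2.9,1.4,0
301-320,F61A-WT-ETS,-1,2.3,1
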