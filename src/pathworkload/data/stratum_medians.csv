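stratum,l4e,w2q,fee,specimen_type
L861_3,0.6175,0.29,14.30,small resections
L864,1.8525,2.00,97.30,most biopsies
L865,5.135,4.04,165.60,intermediate size resections
L866,15.32375,8.29,347.25,large resections
L86x0,1.235,0.56,4.60,uncomplicated cytology
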