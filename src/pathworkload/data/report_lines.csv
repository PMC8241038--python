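year,dx,micro,ccs,sum
2011,407597,104095,95170,606862
2012,422247,80250,147435,649932
2013,400027,77735,145206,622968
2014,408174,64153,150233,622560
2015,429078,62504,156767,648349
2016,448605,66375,155862,670842
2017,451190,62156,164562,677908
2018,445290,57564,191206,694060
2019,447975,80901,194299,723175
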