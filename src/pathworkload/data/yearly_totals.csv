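year,l4e,w2q,sob_fees,blocks,report_lines,ihcs,special_stains,ftes,cases
2011,165276.0,149840.5,6766927.15,236197,606862,40336,15199,30.42,66056
2012,181625.2,159131.7,7122570.15,259095,649932,48448,15860,29.99,67447
2013,186130.0,162329.4,7206866.00,269501,622968,62909,14857,30.18,64039
2014,190637.1,171949.7,7612328.20,274096,622560,79984,14660,30.02,63417
2015,199294.6,178304.4,7840372.25,285925,648349,84132,14559,29.81,65003
2016,196077.6,174116.9,7613806.30,281975,670842,74353,14319,30.32,64671
2017,193285.0,174307.7,7604699.65,281910,677908,70251,14102,30.73,61134
2018,199897.5,176058.5,7551597.25,287437,694060,65023,13165,30.96,60364
2019,203893.6,181321.5,7677109.20,283751,723175,60423,14140,30.77,61962
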