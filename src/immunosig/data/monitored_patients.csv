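patient_id,week,sledai2k,leucocyte_count
P01,0,6,7.0
P01,4,2,7.8
P01,12,2,7.4
P02,0,30,14.4
P02,4,17,4.3
P02,12,17,17.4
P03,0,10,3.8
P03,4,10,6.4
P03,12,10,5.4
P04,0,12,7.5
P04,4,7,7.2
P04,12,10,4.0
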