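hair_id,size_class,length_mm
Z1,short_medium,10.4
Z2,short_medium,9.1
Z3,short_medium,11.4
Z4,short_medium,12.2
Z5,long,17.9
Z6,long,16.8
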