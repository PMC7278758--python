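parameter,treatment,value,reference_predicted
voluntary_dmi,maize_lablab,9.8,14.4
voluntary_dmi,oats_vetch,9.7,14.2
final_body_weight,maize_lablab,386,454
final_body_weight,oats_vetch,399,430
milk_yield,maize_lablab,8.3,13.1
milk_yield,oats_vetch,6.8,12.6
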