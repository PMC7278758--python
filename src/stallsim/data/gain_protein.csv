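sex,species_class,age_years,np_g_per_kg
female,crossbred,0.0,236
female,crossbred,0.1,182
female,crossbred,1.5,174
female,crossbred,3.0,171
female,crossbred,4.5,170
female,crossbred,5.5,170
female,crossbred,20.0,170
female,indicus,0.0,236
female,indicus,0.1,182
female,indicus,1.5,173
female,indicus,3.0,170
female,indicus,4.5,168
female,indicus,5.5,168
female,indicus,20.0,168
male,crossbred,0.0,236
male,crossbred,0.1,182
male,crossbred,1.5,175
male,crossbred,3.0,172
male,crossbred,4.5,170
male,crossbred,5.5,169
male,crossbred,20.0,169
male,indicus,0.0,236
male,indicus,0.1,182
male,indicus,1.5,174
male,indicus,3.0,168
male,indicus,4.5,167
male,indicus,5.5,167
male,indicus,20.0,167
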