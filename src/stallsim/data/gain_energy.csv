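sex,species_class,age_years,ne_mj_per_kg
female,crossbred,0.0,3.4
female,crossbred,0.1,4.0
female,crossbred,1.5,9.6
female,crossbred,3.0,16.5
female,crossbred,4.5,23.4
female,crossbred,5.5,23.4
female,crossbred,20.0,23.4
female,indicus,0.0,3.4
female,indicus,0.1,3.9
female,indicus,1.5,8.6
female,indicus,3.0,12.9
female,indicus,4.5,16.2
female,indicus,5.5,17.0
female,indicus,20.0,17.0
male,crossbred,0.0,3.4
male,crossbred,0.1,4.0
male,crossbred,1.5,9.1
male,crossbred,3.0,15.5
male,crossbred,4.5,21.8
male,crossbred,5.5,25.1
male,crossbred,20.0,25.1
male,indicus,0.0,3.4
male,indicus,0.1,3.9
male,indicus,1.5,7.9
male,indicus,3.0,11.9
male,indicus,4.5,14.8
male,indicus,5.5,18.8
male,indicus,20.0,18.8
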