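relation,percent
general_population,0.9
foster_brothers,1.8
spouses,2.1
first_cousins,2.6
nieces_and_nephews,3.9
grandchildren,4.3
stepbrothers,7.1
parents,9.2
brothers,14.2
dizygotic_twin,14.5
sons_and_daughters,16.4
dizygotic_twin_of_the_same_sex,17.6
children_of_father_and_mother_schizophrenics,39.2
monozygotic_twin_living_separately,77.6
monozygotic_twin_living_together,91.5
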