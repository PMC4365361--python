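record_id,age,sex,relation,drugs,alcohol,somnolence,consciousness,neurological,infectious,toxic_metabolic,thinking_alterations,passivity,hallucinations,delusions,delusional_intuition,perplexity,emotional_impoverishment,dysthymias
patient_2,28,female,?,0,1,1,2,0,1,1,0,0,0,0,0,1,0,0
male_22,22,male,general_population,1,1,1,2,1,1,?,3,0,0,2,0,0,0.25..0.75,0
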