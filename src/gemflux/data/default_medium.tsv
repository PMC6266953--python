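# Default four-substrate growth medium (mmol/gDW/hr).
# Glucose uptake is -10; the -5 bounds on the secondary substrates
# (glutamate, glycerol, pyruvate) are ASSUMPTIONS, not measured values:
# no published uptake rates exist for them in this condition.
# Ids follow the synthetic branched toy's exchange naming.
exchange_reaction_id	lower_bound	upper_bound
EX_glc_e	-10	0
EX_glu_L_e	-5	0
EX_glyc_e	-5	0
EX_pyr_e	-5	0
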