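criterion,label,r_soap,r_abas,entropy,weight
short_time,Short time application,0.43,0.57,0.98,0.22
glove_usage,Glove usage,0.52,0.48,0.99,0.05
dry_cracked_skin,Dry and cracked skin,0.55,0.45,0.99,0.09
workload,Workload of the staff,0.43,0.57,0.98,0.22
easy_to_use,Easy to use,0.41,0.60,0.97,0.35
intervention_type,Intervention type,0.47,0.53,0.99,0.04
efficiency,Efficiency,0.47,0.53,0.99,0.03
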