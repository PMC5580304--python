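item,short_time,glove_usage,dry_cracked_skin,workload,easy_to_use,intervention_type,efficiency
short_time,1,1,1,1,2,1/2,1/4
glove_usage,1,1,1,1,1,2,3
dry_cracked_skin,1,1,1,1,2,2,5
workload,1,1,1,1,1/2,1/2,1/4
easy_to_use,1/2,1,1/2,2,1,1/2,1/4
intervention_type,2,1/2,1/2,2,2,1,1/2
efficiency,4,1/3,1/5,4,4,2,1
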