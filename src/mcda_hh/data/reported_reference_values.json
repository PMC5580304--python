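{
  "comment": "Published summary values from the motivating hand-hygiene study, shipped as reference metadata only. The raw 15-expert responses are unpublished, so none of these can be recomputed here; the reproduce report prints them next to what the bundled fixtures do permit.",
  "maut_total_utility": {"abas": 0.86, "soap": 0.14},
  "ahp_criterion_weights_reported": {
    "efficiency": 0.35,
    "intervention_type": 0.19,
    "easy_to_use": 0.12,
    "dry_cracked_skin": 0.07
  },
  "ahp_combined_cr_reported": 0.01,
  "ahp_global_priorities_reported": {"abas": 0.69, "soap": 0.31},
  "cronbach_alpha_reported": {"maut_form": 0.74, "ahp_form": 0.77}
}
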