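{
 "schema_version": 1,
 "experiment": "reporter_panel",
 "seed": 1,
 "fold_changes": {
  "RgE21": 0.02014776549883388,
  "RgE4": 0.050127347053846694,
  "RgE3": 0.3505240951476825,
  "RgE13": 0.5003349458530287,
  "RgE11": 0.6469554070704922,
  "RgE2": 0.8450497602421463,
  "CMV": 1.0,
  "RgE6": 1.0983507393437795
 },
 "n_gated": {
  "RgE21": 5506,
  "RgE4": 5511,
  "RgE3": 5507,
  "RgE13": 5502,
  "RgE11": 5515,
  "RgE2": 5509,
  "CMV": 5505,
  "RgE6": 5504
 },
 "mrna_fc": {
  "CMV": 1.0,
  "RgE11": 1.15830457573217,
  "RgE13": 1.0251517041867997,
  "RgE2": 0.9778210187988988,
  "RgE21": 1.393060228790719,
  "RgE3": 1.0987868391973836,
  "RgE4": 1.1605244989122776,
  "RgE6": 1.161458583417741
 },
 "rna_protein_ratio": {
  "RgE21": 69.14217007694214,
  "RgE4": 23.151524409732765,
  "RgE3": 3.134697027702029,
  "RgE13": 2.0489308465931813,
  "RgE11": 1.7903932219643097,
  "RgE2": 1.1571164975169124,
  "RgE6": 1.0574569140925476
 },
 "fit_linear": {
  "params": {
   "slope": 0.027872121198601472,
   "intercept": 1.2541887095350697
  },
  "r2": 0.9922013632253065
 },
 "fit_logistic4": {
  "params": {
   "a": 1.704681410794351,
   "d": -0.551606411996587,
   "g50": -24.257445719610146,
   "b": -18.80309018053348
  },
  "r2": 0.9931794395776166
 }
}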