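{
 "feature_list": [
  "d_ppeak",
  "d_pplat",
  "has_pplat",
  "d_ppp",
  "d_pef",
  "d_vt",
  "paw_insp_deform",
  "exp_deform",
  "insp_flow_deform",
  "is_pcv",
  "is_psv"
 ],
 "coefficients": [
  -3.6181684397971616,
  -0.9258928111122945,
  -1.352456372869394,
  -0.8595375926109665,
  -3.31037232565359,
  3.667665237442599,
  1.691173346220505,
  0.9426220011704513,
  2.79726421541383,
  -0.6537779884316354,
  0.0
 ],
 "intercept": 1.297780134144138,
 "scaler_mean": [
  -0.7245494482499194,
  -1.4962447488436803,
  0.551660516605166,
  0.7719942860247121,
  -1.4299792935483366,
  48.519147479819374,
  1.9937965902317842,
  0.13803780868991736,
  0.2467616208392812,
  0.4354243542435424,
  0.0
 ],
 "scaler_scale": [
  1.5403709874632094,
  3.6484944901342478,
  0.4973240302097684,
  2.6517482375974035,
  9.682573741636027,
  133.91850602220367,
  5.097699062713418,
  0.22394315570377796,
  0.7022701658924376,
  0.49581245040351585,
  1.0
 ],
 "cutoff": 0.39362550130028295,
 "training_meta": {
  "seed": 0,
  "n_train": 1084,
  "n_pos": 420,
  "scenario_config_hash": "f8654a4864e3"
 }
}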