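{
 "alpha": [
  0.01,
  0.05
 ],
 "correlation": {
  "T": 13,
  "kind": "exchangeable",
  "rho": 0.6
 },
 "mean": {
  "kind": "null"
 },
 "methods": [
  "scat",
  "fisher"
 ],
 "missingness": {
  "enabled": false
 },
 "n_reps": 100000,
 "out_prefix": "typeI_exch_rho0.6",
 "seed": 1
}
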