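{
 "alpha": 0.05,
 "correlation": {
  "T": 13,
  "kind": "exchangeable",
  "rho": 0.9
 },
 "mean": {
  "kind": "gaussian",
  "variance": 2.5
 },
 "methods": [
  "scat"
 ],
 "missingness": {
  "enabled": true,
  "max": 11,
  "min": 5
 },
 "n_reps": 1000,
 "out_prefix": "power_exch_rho0.9",
 "seed": 1
}
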