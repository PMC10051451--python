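{
 "delta50": {
  "file": "delta50_synthetic_shifts.csv",
  "sha256": "3dce2b5c1b0dbfdd704eb00e9361cf0cc196440529f2d314ff0e116cb8327505",
  "n_compounds": 50,
  "n_sites_h1": 114,
  "n_sites_c13": 143,
  "h1_range_ppm": [
   0.25,
   9.8
  ],
  "c13_range_ppm": [
   -2.9,
   219.4
  ],
  "notes": "synthetic stand-in; diastereotopic terminal-vinyl pair of 3,3-dimethyl-1-butene stored as two H1 sites"
 },
 "probe": {
  "file": "probe_summary.csv",
  "sha256": "e92702ef07b94f502280e0deaad89cf7e92e911134465c2f075218a13695fd8b",
  "n_records": 20,
  "mw_range_g_mol": [
   96,
   854
  ]
 }
}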