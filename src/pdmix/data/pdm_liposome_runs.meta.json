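{
  "description": "29-run central-composite liposome study in the periodic-disturbance micromixer: 4 cube points x3, 4 axial points x3, centre point x5; 9 distinct (frr, tfr) conditions.",
  "units": {"frr": "dimensionless", "tfr": "mL/h", "z_average_nm": "nm", "pdi": "dimensionless", "zeta_mv": "mV"},
  "design": {"alpha": 1.4142135623730951, "frr_axial": [1.0, 12.0], "tfr_axial": [3.0, 18.0], "decimals": 1},
  "corrections": [
    {"run_order": 23, "column": "z_average_nm", "recorded": "110.4.", "stored": 110.4, "reason": "stray trailing period in the source record"},
    {"run_order": 25, "column": "zeta_mv", "recorded": "32.4", "stored": -32.4, "reason": "sign restored; every other zeta value in the series is negative"}
  ]
}
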