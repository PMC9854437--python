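{
 "cannulae": {
  "in_FV": {
   "C": 0.0,
   "L": 0.0,
   "R": 0.0902,
   "role": "in_FV"
  },
  "in_RA": {
   "C": 0.0,
   "L": 0.0,
   "R": 0.2715,
   "role": "in_RA"
  },
  "in_SVC": {
   "C": 0.0,
   "L": 0.0,
   "R": 0.5,
   "role": "in_SVC"
  },
  "out_AA": {
   "C": 0.0,
   "L": 0.0,
   "R": 0.25,
   "role": "out_AA"
  },
  "out_CC": {
   "C": 0.0,
   "L": 0.0,
   "R": 180.0,
   "role": "out_CC"
  },
  "out_FA": {
   "C": 0.0,
   "L": 0.0,
   "R": 1.45,
   "role": "out_FA"
  }
 },
 "chambers": {
  "LA": {
   "E_max": 0.5,
   "E_min": 0.35,
   "V0": 10.0,
   "activation_offset": 0.0,
   "name": "LA"
  },
  "LV": {
   "E_max": 2.371,
   "E_min": 0.3,
   "V0": 15.0,
   "activation_offset": 0.0,
   "name": "LV"
  },
  "RA": {
   "E_max": 0.35,
   "E_min": 0.22,
   "V0": 8.0,
   "activation_offset": 0.0,
   "name": "RA"
  },
  "RV": {
   "E_max": 0.7,
   "E_min": 0.18,
   "V0": 10.0,
   "activation_offset": 0.0,
   "name": "RV"
  }
 },
 "compartments": {
  "AA1": {
   "C": 0.507,
   "L": 0.0,
   "R": 0.04,
   "V_unstressed": 60.0,
   "external_pressure_ref": "intrathoracic",
   "name": "AA1"
  },
  "AA2": {
   "C": 0.455,
   "L": 0.0003,
   "R": 0.08,
   "V_unstressed": 60.0,
   "external_pressure_ref": "intrathoracic",
   "name": "AA2"
  },
  "AB1": {
   "C": 0.455,
   "L": 0.0002,
   "R": 0.06,
   "V_unstressed": 70.0,
   "external_pressure_ref": "abdominal",
   "name": "AB1"
  },
  "ABII": {
   "C": 0.364,
   "L": 0.0002,
   "R": 0.07,
   "V_unstressed": 60.0,
   "external_pressure_ref": "abdominal",
   "name": "ABII"
  },
  "ARM": {
   "C": 0.8,
   "L": 0.0,
   "R": 5.058,
   "V_unstressed": 40.0,
   "external_pressure_ref": "atmospheric",
   "name": "ARM"
  },
  "ARM2": {
   "C": 0.0,
   "L": 0.0,
   "R": 1.9,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "ARM2"
  },
  "AT1": {
   "C": 0.546,
   "L": 0.0003,
   "R": 0.05,
   "V_unstressed": 80.0,
   "external_pressure_ref": "intrathoracic",
   "name": "AT1"
  },
  "AbdVC": {
   "C": 18.377,
   "L": 0.0,
   "R": 0.01,
   "V_unstressed": 300.0,
   "external_pressure_ref": "abdominal",
   "name": "AbdVC"
  },
  "COR": {
   "C": 0.0,
   "L": 0.0,
   "R": 12.991,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "COR"
  },
  "HD": {
   "C": 1.2,
   "L": 0.0,
   "R": 3.0866,
   "V_unstressed": 50.0,
   "external_pressure_ref": "atmospheric",
   "name": "HD"
  },
  "HD2": {
   "C": 0.0,
   "L": 0.0,
   "R": 1.2,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "HD2"
  },
  "HEP": {
   "C": 3.0,
   "L": 0.0,
   "R": 5.058,
   "V_unstressed": 150.0,
   "external_pressure_ref": "abdominal",
   "name": "HEP"
  },
  "HEP2": {
   "C": 0.0,
   "L": 0.0,
   "R": 1.9,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "HEP2"
  },
  "IVC": {
   "C": 38.29,
   "L": 0.0,
   "R": 0.01,
   "V_unstressed": 500.0,
   "external_pressure_ref": "abdominal",
   "name": "IVC"
  },
  "IVC2": {
   "C": 0.0,
   "L": 0.0,
   "R": 0.01,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "IVC2"
  },
  "KID": {
   "C": 2.0,
   "L": 0.0,
   "R": 1.8435,
   "V_unstressed": 60.0,
   "external_pressure_ref": "abdominal",
   "name": "KID"
  },
  "KID2": {
   "C": 0.0,
   "L": 0.0,
   "R": 0.7,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "KID2"
  },
  "LFV": {
   "C": 0.0,
   "L": 0.0,
   "R": 1.8,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "LFV"
  },
  "LLE": {
   "C": 2.0,
   "L": 0.0,
   "R": 4.7296,
   "V_unstressed": 100.0,
   "external_pressure_ref": "atmospheric",
   "name": "LLE"
  },
  "PA": {
   "C": 4.0,
   "L": 5e-05,
   "R": 0.005963,
   "V_unstressed": 80.0,
   "external_pressure_ref": "intrathoracic",
   "name": "PA"
  },
  "PC": {
   "C": 6.0,
   "L": 0.0,
   "R": 0.004764,
   "V_unstressed": 100.0,
   "external_pressure_ref": "intrathoracic",
   "name": "PC"
  },
  "PVEN": {
   "C": 8.0,
   "L": 0.0,
   "R": 0.004764,
   "V_unstressed": 150.0,
   "external_pressure_ref": "intrathoracic",
   "name": "PVEN"
  },
  "RFV": {
   "C": 0.0,
   "L": 0.0,
   "R": 1.8,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "RFV"
  },
  "RLE": {
   "C": 2.0,
   "L": 0.0,
   "R": 4.7296,
   "V_unstressed": 100.0,
   "external_pressure_ref": "atmospheric",
   "name": "RLE"
  },
  "SP": {
   "C": 6.0,
   "L": 0.0,
   "R": 1.4435,
   "V_unstressed": 250.0,
   "external_pressure_ref": "abdominal",
   "name": "SP"
  },
  "SP2": {
   "C": 0.0,
   "L": 0.0,
   "R": 0.55,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "SP2"
  },
  "SVC": {
   "C": 22.971,
   "L": 0.0,
   "R": 0.03,
   "V_unstressed": 250.0,
   "external_pressure_ref": "intrathoracic",
   "name": "SVC"
  },
  "THOR": {
   "C": 0.0,
   "L": 0.0,
   "R": 0.05,
   "V_unstressed": 0.0,
   "external_pressure_ref": "atmospheric",
   "name": "THOR"
  }
 },
 "environment": {
  "P_B": 0.0,
  "P_abdominal": 0.0,
  "Pt": -4.0
 },
 "pump": {
  "k1": 1.6e-05,
  "k2": 0.0009,
  "k3": 0.0014,
  "speed": 0.0
 },
 "resistance_scales": {},
 "septum": {
  "E_spt_max": 4.8,
  "E_spt_min": 0.58
 },
 "timing": {
  "AV_delay": null,
  "HR": 90.0,
  "T_sys_atrial": null,
  "T_sys_ventricular": null
 },
 "valves": {
  "AV": {
   "R_open": 0.005,
   "name": "AV"
  },
  "MV": {
   "R_open": 0.003,
   "name": "MV"
  },
  "PV": {
   "R_open": 0.005,
   "name": "PV"
  },
  "TV": {
   "R_open": 0.003,
   "name": "TV"
  }
 },
 "volume_adjust": -90.0
}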