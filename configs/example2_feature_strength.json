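{
  "name": "example2",
  "design": {"kind": "relu_regression", "N": 6000, "d": 100, "B": 0.4, "r": 0.25,
             "s0_size": 5, "L": 3, "width": 128, "tau": 8.0},
  "variants": [
    {"design": {"B": 0.2}, "name_suffix": "_B0.2"},
    {"design": {"B": 0.4}, "name_suffix": "_B0.4"},
    {"design": {"B": 0.6}, "name_suffix": "_B0.6"}
  ],
  "hf_cases": ["i", "ii", "iii", "iv"],
  "tests": [
    {"kind": "one_split", "split": "fixed:0.5", "rho": 0.1, "learner": "mlp:width=128"},
    {"kind": "two_split", "split": "fixed:0.5", "learner": "mlp:width=128"},
    {"kind": "one_split", "split": "fixed:0.5", "rho": 0.1, "learner": "mlp:width=128",
     "combine": "hommel", "U": 5},
    {"kind": "two_split", "split": "fixed:0.5", "learner": "mlp:width=128",
     "combine": "hommel", "U": 5}
  ],
  "reps_h0": 1000,
  "reps_ha": 100,
  "alpha": 0.05
}
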