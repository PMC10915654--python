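{
  "name": "example1",
  "design": {"kind": "relu_regression", "N": 2000, "d": 100, "B": 0.4, "r": 0.25,
             "s0_size": 5, "L": 3, "width": 128, "tau": 8.0},
  "variants": [
    {"design": {"N": 2000}, "name_suffix": "_N2000"},
    {"design": {"N": 6000}, "name_suffix": "_N6000"},
    {"design": {"N": 10000}, "name_suffix": "_N10000"}
  ],
  "hf_cases": ["i", "ii", "iii", "iv"],
  "tests": [
    {"kind": "one_split", "split": "log-ratio", "rho": 0.01, "learner": "mlp:width=128"},
    {"kind": "two_split", "split": "log-ratio", "learner": "mlp:width=128"},
    {"kind": "one_split", "split": "log-ratio", "rho": 0.01, "learner": "mlp:width=128",
     "combine": "hommel", "U": 5},
    {"kind": "two_split", "split": "log-ratio", "learner": "mlp:width=128",
     "combine": "hommel", "U": 5}
  ],
  "reps_h0": 1000,
  "reps_ha": 100,
  "alpha": 0.05
}
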