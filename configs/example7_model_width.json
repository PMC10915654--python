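{
  "name": "example7",
  "design": {"kind": "relu_regression", "N": 6000, "d": 100, "B": 0.4, "r": 0.25,
             "s0_size": 5, "L": 3, "width": 64, "tau": 8.0},
  "hf_cases": ["i", "ii", "iii", "iv"],
  "tests": [
    {"kind": "one_split", "split": "fixed:0.5", "rho": 0.1, "learner": "mlp:width=32"},
    {"kind": "one_split", "split": "fixed:0.5", "rho": 0.1, "learner": "mlp:width=64"},
    {"kind": "one_split", "split": "fixed:0.5", "rho": 0.1, "learner": "mlp:width=128"},
    {"kind": "two_split", "split": "fixed:0.5", "learner": "mlp:width=32"},
    {"kind": "two_split", "split": "fixed:0.5", "learner": "mlp:width=64"},
    {"kind": "two_split", "split": "fixed:0.5", "learner": "mlp:width=128"}
  ],
  "reps_h0": 1000,
  "reps_ha": 100,
  "alpha": 0.05
}
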