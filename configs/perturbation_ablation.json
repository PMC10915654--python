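{
  "name": "ablation",
  "design": {"kind": "partial_feature", "N": 2000, "d": 100, "B": 0.4,
             "s0_size": 3, "L": 3, "width": 128, "tau": 8.0},
  "variants": [
    {"design": {"N": 2000}, "name_suffix": "_N2000"},
    {"design": {"N": 6000}, "name_suffix": "_N6000"},
    {"design": {"N": 10000}, "name_suffix": "_N10000"}
  ],
  "hf_cases": ["i"],
  "tests": [
    {"kind": "one_split", "split": "fixed:0.2", "rho": 0.0, "learner": "mlp:width=128"},
    {"kind": "one_split", "split": "fixed:0.2", "rho": 1.0, "learner": "mlp:width=128"},
    {"kind": "two_split", "split": "fixed:0.2", "learner": "mlp:width=128"}
  ],
  "reps_h0": 1000,
  "alpha": 0.05
}
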