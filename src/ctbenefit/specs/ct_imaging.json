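{
  "name": "ct_imaging",
  "terms": [
    {"kind": "treatment", "variable": "evt"},
    {"kind": "linear", "variable": "aspects"},
    {"kind": "categorical", "variable": "occlusion"},
    {"kind": "linear", "variable": "collateral"},
    {"kind": "linear", "variable": "wml_volume", "scale": 5.0},
    {"kind": "spline", "variable": "bpf", "forced_middle": 80.0},
    {"kind": "categorical", "variable": "icac"},
    {"kind": "interaction", "variable": "evt", "with_variable": "collateral"}
  ]
}
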