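{
  "name": "mr_predicts_ref",
  "terms": [
    {"kind": "treatment", "variable": "evt"},
    {"kind": "spline", "variable": "age", "forced_middle": 65.0},
    {"kind": "linear", "variable": "nihss"},
    {"kind": "spline", "variable": "sbp", "forced_middle": 130.0},
    {"kind": "linear", "variable": "iv_alteplase"},
    {"kind": "linear", "variable": "diabetes"},
    {"kind": "spline", "variable": "glucose", "forced_middle": 120.0},
    {"kind": "linear", "variable": "prestroke_mrs"},
    {"kind": "linear", "variable": "onset_to_groin", "scale": 30.0},
    {"kind": "linear", "variable": "aspects"},
    {"kind": "categorical", "variable": "occlusion"},
    {"kind": "linear", "variable": "collateral"},
    {"kind": "interaction", "variable": "evt", "with_variable": "collateral"}
  ]
}
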