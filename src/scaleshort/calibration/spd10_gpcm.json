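{
  "instrument": "SPD-10 (chronic renal failure specific module of the QLICD-CRF V2.0)",
  "model": "generalized partial credit model, theta ~ N(0, 1)",
  "n_categories": 5,
  "items": [
    {"item_id": "CRF1", "alpha": 0.704, "betas": [-2.061, -0.731, -2.360, -0.049]},
    {"item_id": "CRF2", "alpha": 0.789, "betas": [-1.743, -0.280, -1.199, 1.858]},
    {"item_id": "CRF3", "alpha": 0.707, "betas": [-0.921, -0.177, -0.862, 0.615]},
    {"item_id": "CRF4", "alpha": 0.661, "betas": [-1.055, -1.790, -1.351, 0.850]},
    {"item_id": "CRF5", "alpha": 0.572, "betas": [-0.488, -1.669, -1.461, 0.168]},
    {"item_id": "CRF6", "alpha": 0.987, "betas": [-1.681, -0.915, -1.594, 0.190]},
    {"item_id": "CRF7", "alpha": 0.194, "betas": [-2.969, -2.959, -0.955, 3.232]},
    {"item_id": "CRF8", "alpha": 0.686, "betas": [-1.755, -1.207, -0.831, 1.453]},
    {"item_id": "CRF9", "alpha": 0.849, "betas": [-0.831, -0.921, -0.414, 1.227]},
    {"item_id": "CRF10", "alpha": 0.522, "betas": [-1.094, -1.381, -0.912, 0.268]}
  ]
}
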