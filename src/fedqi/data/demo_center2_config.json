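{
  "center_id": "center2",
  "n_patients": 40,
  "seed": 202,
  "quota_counts": {
    "colon": [10, 7],
    "rectum": [7, 4]
  }
}
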