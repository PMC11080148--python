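{
  "center_id": "center1",
  "n_patients": 4699,
  "seed": 201,
  "quota_counts": {
    "colon": [546, 546],
    "rectum": [4153, 2144]
  }
}
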