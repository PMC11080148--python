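{
  "center_id": "center_demo",
  "n_patients": 200,
  "seed": 7,
  "rectum_fraction": 0.45,
  "referred_fraction": 0.1,
  "neoadjuvant_fraction": 0.3,
  "complication_prob": 0.3,
  "short_wait_fraction": null,
  "waiting_time_days": {"name": "uniform_int", "low": 7, "high": 62},
  "quota_counts": null,
  "age": {"name": "normal", "mean": 68.0, "sd": 11.0, "low": 18, "high": 95},
  "bmi": {"name": "lognormal", "mean_log": 3.26, "sd_log": 0.15, "low": 15, "high": 50},
  "charlson": {"name": "poisson", "lam": 1.2, "high": 12},
  "asa": {"name": "categorical", "values": {"1": 0.12, "2": 0.55, "3": 0.28, "4": 0.045, "5": 0.005}},
  "preop_complication": {"name": "bernoulli", "p": 0.25}
}
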