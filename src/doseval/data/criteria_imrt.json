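{
  "name": "IMRT clinical objectives (78 Gy in 39 fractions)",
  "rules": [
    {"structure": "PTV", "metric": {"kind": "V", "dose_pct_pd": 95}, "op": ">", "limit": 95, "units": "%",
     "note": ">95% of the PTV receives at least 95% of the PD"},
    {"structure": "PTV", "metric": {"kind": "D", "volume_pct": 2}, "op": "<=", "limit": 81.9, "units": "Gy",
     "note": "D2% <= 105% of 78 Gy"},
    {"structure": "rectum", "metric": {"kind": "V", "dose_gy": 50}, "op": "<", "limit": 50, "units": "%"},
    {"structure": "bladder", "metric": {"kind": "V", "dose_gy": 65}, "op": "<", "limit": 50, "units": "%"},
    {"structure": "RFH", "metric": {"kind": "Dmean"}, "op": "<", "limit": 37, "units": "Gy"},
    {"structure": "RFH", "metric": {"kind": "Dmax"}, "op": "<", "limit": 55, "units": "Gy"},
    {"structure": "LFH", "metric": {"kind": "Dmean"}, "op": "<", "limit": 37, "units": "Gy"},
    {"structure": "LFH", "metric": {"kind": "Dmax"}, "op": "<", "limit": 55, "units": "Gy"}
  ]
}
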