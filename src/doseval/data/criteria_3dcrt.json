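{
  "name": "3D-CRT clinical objectives (70 Gy prescription)",
  "rules": [
    {"structure": "CTV", "metric": {"kind": "V", "dose_pct_pd": 100}, "op": ">=", "limit": 100, "units": "%",
     "note": "100% of the CTV receives at least 100% of the prescribed dose"},
    {"structure": "PTV", "metric": {"kind": "V", "dose_pct_pd": 95}, "op": ">", "limit": 95, "units": "%",
     "note": ">95% of the PTV receives at least 95% of the PD"},
    {"structure": "bladder", "metric": {"kind": "V", "dose_gy": 50}, "op": "<", "limit": 50, "units": "%"},
    {"structure": "bladder", "metric": {"kind": "V", "dose_gy": 65}, "op": "<", "limit": 50, "units": "%"},
    {"structure": "rectum", "metric": {"kind": "V", "dose_gy": 50}, "op": "<", "limit": 50, "units": "%"},
    {"structure": "rectum", "metric": {"kind": "V", "dose_gy": 65}, "op": "<", "limit": 25, "units": "%",
     "note": "source threshold ambiguous; <25% is an encoding choice, review before clinical use"},
    {"structure": "RFH", "metric": {"kind": "Dmean"}, "op": "<", "limit": 37, "units": "Gy"},
    {"structure": "RFH", "metric": {"kind": "Dmax"}, "op": "<", "limit": 55, "units": "Gy"},
    {"structure": "LFH", "metric": {"kind": "Dmean"}, "op": "<", "limit": 37, "units": "Gy"},
    {"structure": "LFH", "metric": {"kind": "Dmax"}, "op": "<", "limit": 55, "units": "Gy"}
  ]
}
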