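"""Small end-to-end study: cohort generation, evaluation, paired statistics.

Generates a 5-case cohort with three contour sets each (reference OC,
simulated expert EC, simulated auto-contour AC) and one plan per set, runs
the full pipeline, and prints the study-style summary tables.
"""

from doseval import generate_cohort, run_pipeline

cohort = generate_cohort(n=5, seed=7, technique="box4")
result = run_pipeline(cohort, out_dir="pipeline_reports")

print("DSC summary (mean over 5 cases):")
cols = ["structure", "dsc_EC-OC_mean", "dsc_AC-OC_mean", "dsc_AC-EC_mean"]
print(result.dsc_summary[cols].round(2).to_string(index=False))

print("\nPTV dosimetric comparison (Wilcoxon signed-rank p for paired sets):")
ptv = result.comparison[result.comparison["structure"] == "PTV"]
cols = ["metric", "ec_mean", "oc_mean", "ac_mean", "d_ac_oc_mean", "p_ac_oc"]
print(ptv[cols].round(3).to_string(index=False))

print("\ngamma pass rates, auto-contour plan vs reference plan (3%/3 mm):")
print(result.gamma[["case", "pass_rate_pct"]].round(2).to_string(index=False))

print("\nfull CSV/JSON reports written to pipeline_reports/")
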