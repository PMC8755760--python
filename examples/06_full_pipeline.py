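"""Run the whole synthetic study end to end and print the headline report.

Equivalent to `stopthink all --seed 5 --out scratch/demo-study` from a
shell.  Resample counts are scaled down for a quick demonstration.
"""

from stopthink.pipeline import StudyConfig, run_pipeline

cfg = StudyConfig(seed=5, out_dir="scratch/demo-study",
                  pls_n_perm=200, pls_n_boot=200, mvpa_n_subsets=10,
                  bms_n_samples=50_000)
report = run_pipeline(cfg)

b = report["behavior"]
print(f"behaviour : SSRT {b['group_mean_ssrt_ms']:.1f} ms, "
      f"SIF {b['group_mean_sif']:.3f}, "
      f"SSRT-SIF {b['ssrt_sif_correlation'].method} "
      f"r = {b['ssrt_sif_correlation'].estimate:.3f}")
print(f"timecourse: interaction F = {report['timecourse']['interaction_f']:.1f}")
for roi, inf in report["mvpa"]["cross_task"].items():
    print(f"mvpa      : {roi:12s} cross-task {inf.mean_accuracy * 100:.1f}% "
          f"(p_adj = {inf.test.p:.4f})")
ep = dict(zip(report["bms"]["targets"]["labels"],
              report["bms"]["targets"]["exceedance_prob"]))
print(f"bms       : preferred-targets exceedance = {ep['preferred']:.3f}")
print(f"full report and stage tables: {cfg.out_dir}/")
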