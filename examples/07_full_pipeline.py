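"""Run the complete pipeline on a desk-scale synthetic cohort.

simulate → behavioral exclusions/mixture/bias → gaze towardness →
cue-locked and response-locked lateralization with cluster statistics →
onset-resolved reselection summary → cross-correlation lags. All outputs
are written as CSV/JSON under the configured directory, with a provenance
record; reruns with the same seed are byte-identical.
"""

import wmreselect as w

cfg = w.RunConfig(seed=7, out_dir="scratch/example_run", n_participants=8,
                  n_trials_per_participant=144, n_permutations=512,
                  make_figures=True)
bundle = w.run_full(cfg)

summary = bundle["spectral"]["onset_summary"]
print("\nonset-resolved alpha reselection:")
print(summary[["interrupter_onset_ms", "n_significant_clusters",
               "reselection_onset_ms"]].to_string())
print(f"reselection onsets strictly ordered early<medium<late: "
      f"{summary.attrs['ordered']}")
print("(reselection follows each interrupter onset by roughly the ~400-ms "
      "simulated reaction time: evidence for immediate, not just-in-time, "
      "reselection)")

test = bundle["crosscorr"]["zero_lag_test"]
print(f"\nvisual-vs-motor peak lags vs 0: t({test.df})={test.t:.2f}, "
      f"p={test.p:.3f} (synchronous generators -> no latency difference)")
print(f"\noutputs in {bundle['out_dir']}")
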