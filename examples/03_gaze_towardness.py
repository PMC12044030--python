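"""Gaze preprocessing and the towardness statistic.

Raw binocular traces are blink-interpolated (±100 ms), eye-averaged,
downsampled to 250 Hz, fixation-filtered at ±2.75°, smoothed over 15
samples and baselined to −200–0 ms. Towardness is half the difference
between mean horizontal gaze on right- and left-cued trials: positive
values mean gaze leans toward the memorized item.
"""

import numpy as np

import wmreselect as w

cfg = w.TaskConfig(n_participants=1, n_trials_per_participant=216, seed=3)
table = w.make_trial_table(cfg)
raw = w.sample_gaze(table, cfg, towardness_amp=0.15, blink_rate=0.1, seed=3)
print(f"synthetic blinks inserted: {sum(len(b) for b in raw.blink_intervals)}")

ep = w.preprocess_gaze(raw)
print(f"trials retained by the fixation filter: {ep.x.shape[0]}/{ep.n_input_trials}")

surv = table.loc[ep.table_index]
sides = surv["cued_side"].to_numpy()
tw = w.towardness(ep.x[sides == "right"], ep.x[sides == "left"])
peak_i = np.argmax(tw)
print(f"towardness peak: {tw[peak_i]:.3f} deg at {ep.times_ms[peak_i]:.0f} ms "
      "post-cue")
print("(the generator planted a 0.15 deg cue-locked deflection — fixational "
      "gaze leans a fraction of a degree toward the cued item, far below "
      "the 5.5 deg stimulus eccentricity)")
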