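"""Do visual and motor reselection move together? Cross-correlation lags.

Per participant, the normalized cross-correlation z[k] = Σ x[i]·y[i−k]
(scaled into [−1, 1]) between the response-locked alpha (visual) and beta
(motor) band courses is computed over all lags; the lag of the peak
coefficient is tested against zero. Sign convention: if the motor course
lags the visual course by d ms, peaks occur at −d.
"""

import numpy as np

import wmreselect as w

for delay in (0.0, 100.0):
    _, visual, motor = w.sample_reselection_courses(
        n_participants=20, motor_delay_ms=delay, seed=8)
    lags = [w.peak_lag(w.normalized_xcorr(v, m, dt_ms=4.0, per_lag=True))
            for v, m in zip(visual, motor)]
    test = w.zero_lag_test(lags)
    print(f"planted motor delay {delay:.0f} ms -> "
          f"mean peak lag {np.mean(lags):+.1f} ms, "
          f"t({test.df})={test.t:.2f}, p={test.p:.3f}")

print("\nsynchronous generators give lags centered on zero (no latency "
      "difference); a planted 100-ms motor delay is recovered at -100 ms "
      "with the sign the formula implies.")

course = np.sin(np.linspace(0, np.pi, 50)) * -8.0
print(f"\npercent-of-peak scaling: course extreme {course.min():.1f} -> "
      f"{w.normalize_to_peak(course).min():.0f}")
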