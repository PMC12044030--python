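"""Advisory figures for pipeline runs. All statistics are read from the
numeric tables; these plots exist for eyeballing a run."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["standard_figures"]


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def standard_figures(bundle: dict, out) -> None:
    if "behavior" in bundle:
        curve = bundle["behavior"]["curve"]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.axhline(0, color="k", lw=0.5)
        ax.plot(curve.bin_centers, curve.mean)
        ax.set_xlabel("interrupter − target difference (°)")
        ax.set_ylabel("response bias (°)")
        _save(fig, out / "fig_bias_curve.png")

    if "gaze" in bundle:
        fig, ax = plt.subplots(figsize=(5, 3))
        for cond, (mat, _) in bundle["gaze"]["by_onset"].items():
            ax.plot(bundle["gaze"]["times_ms"], mat.mean(axis=0), label=cond)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("time from cue (ms)")
        ax.set_ylabel("towardness (°)")
        ax.legend(fontsize=7)
        _save(fig, out / "fig_towardness.png")

    if "spectral" in bundle:
        spec = bundle["spectral"]
        fig, ax = plt.subplots(figsize=(5, 3))
        for cond, course in spec["courses_by_onset"].items():
            ax.plot(course.times_ms, course.course.mean(axis=0), label=cond)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("time from cue (ms)")
        ax.set_ylabel("alpha lateralization (%)")
        ax.legend(fontsize=7)
        _save(fig, out / "fig_alpha_courses.png")

        fig, ax = plt.subplots(figsize=(4, 3))
        a, b = spec["alpha_response_locked"], spec["beta_response_locked"]
        ax.plot(a.times_ms, a.course.mean(axis=0), label="alpha (visual)")
        ax.plot(b.times_ms, b.course.mean(axis=0), label="beta (motor)")
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5, ls="--")
        ax.set_xlabel("time from interrupter response (ms)")
        ax.set_ylabel("lateralization (%)")
        ax.legend(fontsize=7)
        _save(fig, out / "fig_response_locked.png")
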