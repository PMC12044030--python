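"""Synthetic task data with known ground truth.

Emulates a retro-cue working-memory experiment with a perceptual
interrupting task: two lateralized tilted bars are memorized, a retro-cue
selects one, an interrupter stimulus may appear at one of three onsets
(600 / 1,400 / 2,400 ms post-cue) demanding its own speeded response, and
the cued tilt is reproduced at the probe (3,200 ms). Cued side and response
hand are counterbalanced so visual (location) and motor (hand) signatures
are orthogonal in the trial average.

Four generators cover the downstream stages:

* :func:`make_trial_table` — balanced design table,
* :func:`sample_reports` — continuous orientation reports from a
  target / nontarget(swap) / guess mixture with an optional attractive
  bias toward the interrupter orientation,
* :func:`sample_gaze` — binocular gaze traces with a towardness deflection
  and synthetic blinks,
* :func:`sample_epochs` — multichannel epochs: 1/f background plus
  band-limited alpha/beta oscillations whose contralateral amplitude is
  attenuated inside cue- or response-locked windows,
* :func:`sample_reselection_courses` — response-locked visual/motor band
  courses for lag analyses.

Every generator is fully determined by (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .circular import signed_orientation_diff, wrap_orientation
from .containers import EpochArray, hemisphere

__all__ = [
    "TaskConfig",
    "EffectWindow",
    "NeuralEffectSpec",
    "GazeRaw",
    "default_neural_effects",
    "make_trial_table",
    "sample_reports",
    "sample_gaze",
    "sample_epochs",
    "sample_reselection_courses",
    "kappa_from_sd_deg",
]

_SIDES = ("left", "right")


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the simulated experiment."""

    n_participants: int = 30
    n_trials_per_participant: int = 648
    interrupter_onsets_ms: tuple = (600.0, 1400.0, 2400.0)
    epoch_window_ms: tuple = (-200.0, 4200.0)
    sampling_rate_hz: float = 250.0
    probe_time_ms: float = 3200.0
    block_size: int = 24
    interrupter_rt_mean_ms: float = 400.0
    interrupter_rt_sd_ms: float = 50.0
    interrupter_rt_bounds_ms: tuple = (100.0, 800.0)
    interrupter_p_correct: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0 or self.n_trials_per_participant <= 0:
            raise ValueError("participant and trial counts must be positive")
        onsets = tuple(float(o) for o in self.interrupter_onsets_ms)
        if list(onsets) != sorted(set(onsets)):
            raise ValueError("interrupter onsets must be strictly increasing")
        lo, hi = self.epoch_window_ms
        if not all(lo < o < hi for o in onsets):
            raise ValueError("interrupter onsets must lie inside the epoch window")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.block_size % 4 != 0:
            raise ValueError("block size must be divisible by the 4 side×hand cells")

    @property
    def onset_labels(self) -> dict:
        names = ("early", "medium", "late")
        return {float(o): names[i] for i, o in enumerate(self.interrupter_onsets_ms)}

    def times_ms(self) -> np.ndarray:
        lo, hi = self.epoch_window_ms
        dt = 1000.0 / self.sampling_rate_hz
        n = int(round((hi - lo) / dt)) + 1
        return lo + dt * np.arange(n)


@dataclass(frozen=True)
class EffectWindow:
    """One attenuation window, locked to the cue or the interrupter response.

    ``end_ms=None`` means: for a cue-locked sustained window, until the
    interrupter onset (or the epoch end on no-interruption trials); for a
    response-locked sustained window, until the epoch end.
    """

    start_ms: float
    end_ms: float | None
    profile: str = "transient"  # 'transient' | 'sustained'
    lock: str = "cue"  # 'cue' | 'response'

    def __post_init__(self):
        if self.profile not in ("transient", "sustained"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.lock not in ("cue", "response"):
            raise ValueError(f"unknown lock {self.lock!r}")
        if self.profile == "transient" and self.end_ms is None:
            raise ValueError("transient windows need an explicit end")


@dataclass(frozen=True)
class NeuralEffectSpec:
    """Band-limited oscillation with lateralized attenuation.

    The oscillation is present on both channels of ``channel_pair``; inside
    each window its amplitude on the channel *contralateral* to the relevant
    trial feature (cued side for ``basis='item-side'``, response hand for
    ``basis='response-hand'``) is multiplied by ``1 − contra_attenuation``.
    """

    band: tuple = (8.0, 12.0)
    channel_pair: tuple = ("PO7", "PO8")
    basis: str = "item-side"
    contra_attenuation: float = 0.3
    windows: tuple = (EffectWindow(200.0, 700.0, "transient", "cue"),)
    osc_amplitude: float = 0.5
    motor_delay_ms: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.contra_attenuation < 1.0:
            raise ValueError("contra_attenuation must be in [0, 1)")
        if self.basis not in ("item-side", "response-hand"):
            raise ValueError(f"unknown basis {self.basis!r}")
        object.__setattr__(self, "windows", tuple(self.windows))


def default_neural_effects(alpha_attenuation: float = 0.3,
                           beta_attenuation: float = 0.3,
                           motor_delay_ms: float = 0.0) -> list[NeuralEffectSpec]:
    """The study-pattern defaults.

    Transient posterior alpha attenuation contralateral to the cued item
    after the cue and again after the interrupter response; sustained
    central beta attenuation contralateral to the response hand that pauses
    while the interrupter is handled and re-engages at its response.
    """
    alpha = NeuralEffectSpec(
        band=(8.0, 12.0), channel_pair=("PO7", "PO8"), basis="item-side",
        contra_attenuation=alpha_attenuation,
        windows=(EffectWindow(200.0, 700.0, "transient", "cue"),
                 EffectWindow(0.0, 600.0, "transient", "response")),
    )
    beta = NeuralEffectSpec(
        band=(13.0, 30.0), channel_pair=("C3", "C4"), basis="response-hand",
        contra_attenuation=beta_attenuation,
        windows=(EffectWindow(300.0, None, "sustained", "cue"),
                 EffectWindow(0.0, None, "sustained", "response")),
        motor_delay_ms=motor_delay_ms,
    )
    return [alpha, beta]


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def kappa_from_sd_deg(sd_deg: float) -> float:
    """Von Mises concentration (on doubled angles) for a report SD in
    orientation degrees, via the wrapped-normal approximation κ ≈ 1/σ²."""
    sigma = np.deg2rad(2.0 * sd_deg)
    return 1.0 / sigma**2


# ---------------------------------------------------------------------------
# trial table

def _block_plan(n_trials: int, cfg: TaskConfig) -> list[dict]:
    """Block sequence cycling [no-interruption, fixed, variable]; fixed-block
    onsets rotate through the three onset times."""
    n_blocks = int(np.ceil(n_trials / cfg.block_size))
    plan, n_fixed = [], 0
    for b in range(n_blocks):
        kind = ("no-interruption", "fixed", "variable")[b % 3]
        if kind == "fixed":
            onset = float(cfg.interrupter_onsets_ms[n_fixed % len(cfg.interrupter_onsets_ms)])
            n_fixed += 1
        else:
            onset = None
        plan.append({"kind": kind, "onset": onset})
    return plan


def _participant_rows(pid: int, cfg: TaskConfig, rng: np.random.Generator) -> list[dict]:
    rows = []
    plan = _block_plan(cfg.n_trials_per_participant, cfg)
    remaining = cfg.n_trials_per_participant
    trial = 0
    for b, blk in enumerate(plan):
        size = min(cfg.block_size, remaining)
        remaining -= size
        # balanced side×hand cells, shuffled within block
        cells = [c for _ in range(int(np.ceil(size / 4)))
                 for c in product(_SIDES, _SIDES)][:size]
        order = rng.permutation(size)
        # orthogonal interrupter tilt sign: half matched, half mismatched
        match = np.array([True, False] * int(np.ceil(size / 2)))[:size]
        rng.shuffle(match)
        if blk["kind"] == "variable":
            onsets = np.resize(np.asarray(cfg.interrupter_onsets_ms, float),
                               size)
            rng.shuffle(onsets)
        for j, k in enumerate(order):
            side, hand = cells[k]
            interrupted = blk["kind"] != "no-interruption"
            onset = (blk["onset"] if blk["kind"] == "fixed"
                     else (float(onsets[j]) if blk["kind"] == "variable" else np.nan))
            mag = float(rng.integers(10, 81))
            target = mag if hand == "right" else -mag
            if interrupted:
                imag = float(rng.integers(10, 81))
                isign = np.sign(target) if match[j] else -np.sign(target)
                interrupter = isign * imag
            else:
                interrupter = np.nan
            rows.append({
                "participant": pid, "trial": trial, "block": b,
                "block_type": "interruption" if interrupted else "no-interruption",
                "predictability": blk["kind"] if interrupted else "none",
                "onset_condition": (cfg.onset_labels[onset] if interrupted else "none"),
                "onset_ms": onset,
                "cued_side": side, "response_hand": hand,
                "target_orientation": target,
                "interrupter_orientation": interrupter,
            })
            trial += 1
    return rows


def make_trial_table(cfg: TaskConfig) -> pd.DataFrame:
    """Balanced trial table for the whole cohort.

    Within every onset condition the four {cued_side}×{response_hand}
    cells have equal expected counts, and the tilt sign ↔ response hand
    mapping (leftward/anticlockwise tilt ↔ left hand) holds on every row.
    """
    all_rows = []
    for pid in range(cfg.n_participants):
        rng = _rng(cfg.seed, 1, pid)
        all_rows.extend(_participant_rows(pid, cfg, rng))
    table = pd.DataFrame(all_rows)

    rng = _rng(cfg.seed, 1, cfg.n_participants)
    n = len(table)
    interrupted = table["block_type"].to_numpy() == "interruption"
    lo, hi = cfg.interrupter_rt_bounds_ms
    mu, sd = cfg.interrupter_rt_mean_ms, cfg.interrupter_rt_sd_ms
    tn = sp_stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
    rt = tn.rvs(size=n, random_state=rng)
    table["interrupter_rt_ms"] = np.where(interrupted, rt, np.nan)
    correct = rng.random(n) < cfg.interrupter_p_correct
    table["interrupter_correct"] = np.where(interrupted, correct, np.nan)
    table["rt_probe_ms"] = rng.lognormal(np.log(1000.0), 0.25, size=n)
    table["reported_orientation"] = np.nan
    return table


# ---------------------------------------------------------------------------
# behavioral reports

def _attractive_shift(diff_deg: np.ndarray, gain: float, width: float) -> np.ndarray:
    """Derivative-of-Gaussian bias: odd in the target–interrupter difference,
    peak magnitude ``gain`` at ``diff = ±width``."""
    u = diff_deg / width
    return gain * u * np.exp(0.5 * (1.0 - u**2))


def sample_reports(table: pd.DataFrame, p_target: float = 0.95,
                   p_nontarget: float = 0.02, p_guess: float = 0.03,
                   kappa: float = kappa_from_sd_deg(10.0),
                   bias_gain: float = 0.0, bias_width_deg: float = 20.0,
                   seed: int = 0) -> pd.DataFrame:
    """Fill ``reported_orientation`` with mixture-model draws.

    With probability ``p_target`` the report is a circular-normal (von
    Mises on doubled angles) around the target — shifted toward the
    interrupter by a derivative-of-Gaussian function of the
    target–interrupter difference when ``bias_gain > 0``; with
    ``p_nontarget`` around the interrupter orientation (a swap); with
    ``p_guess`` uniform on the orientation circle. Trials without an
    interrupter fold the swap probability into the target component.
    """
    probs = np.array([p_target, p_nontarget, p_guess], float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("mixture proportions must be nonnegative and sum to 1")
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    rng = _rng(seed, 2)
    out = table.copy()
    n = len(out)
    target = out["target_orientation"].to_numpy(float)
    interrupter = out["interrupter_orientation"].to_numpy(float)
    has_int = np.isfinite(interrupter)

    comp = rng.choice(3, size=n, p=probs)
    comp[(comp == 1) & ~has_int] = 0  # no interrupter → no swap possible

    shift = np.zeros(n)
    if bias_gain != 0.0:
        d = signed_orientation_diff(interrupter[has_int], target[has_int])
        shift[has_int] = _attractive_shift(d, bias_gain, bias_width_deg)

    center = np.where(comp == 1, interrupter, target + shift)
    if np.isinf(kappa):
        noise = np.zeros(n)
    else:
        noise = rng.vonmises(0.0, kappa, size=n)  # doubled-angle radians
    reported = wrap_orientation(center + np.rad2deg(noise) / 2.0)
    guess = wrap_orientation(rng.uniform(-90.0, 90.0, size=n))
    out["reported_orientation"] = np.where(comp == 2, guess, reported)
    return out


# ---------------------------------------------------------------------------
# gaze

@dataclass
class GazeRaw:
    """Raw binocular gaze traces for one set of trials (degrees v.a.)."""

    x_left: np.ndarray
    x_right: np.ndarray
    y_left: np.ndarray
    y_right: np.ndarray
    times_ms: np.ndarray
    rate_hz: float
    blink_intervals: list  # per trial: list of (start_ms, end_ms)
    table_index: np.ndarray  # row labels of the trial table


def _ou_noise(rng, shape, sd, tau_ms, dt_ms):
    """Ornstein–Uhlenbeck (AR(1)) noise with stationary variance sd²."""
    a = np.exp(-dt_ms / tau_ms)
    white = rng.standard_normal(shape)
    out = sp_signal.lfilter([np.sqrt(1 - a**2)], [1.0, -a], white, axis=-1)
    return sd * out


def sample_gaze(table: pd.DataFrame, cfg: TaskConfig,
                towardness_amp: float = 0.1, blink_rate: float = 0.05,
                raw_rate_hz: float = 1000.0, noise_sd: float = 0.3,
                noise_tau_ms: float = 200.0, blink_value: float = -30.0,
                seed: int | None = None) -> GazeRaw:
    """Binocular gaze traces for the trials in ``table``.

    Horizontal position carries a cue-locked and (on interruption trials)
    an interrupter-response-locked Gaussian deflection of peak amplitude
    ``towardness_amp`` signed by the cued side, on top of slow fixational
    drift; blinks saturate both eyes at ``blink_value``. Typically called
    per participant to bound memory.
    """
    if towardness_amp >= 2.75:
        raise ValueError("towardness amplitude must stay well inside the "
                         "±2.75° fixation window")
    rng = _rng(cfg.seed if seed is None else seed, 3)
    dt = 1000.0 / raw_rate_hz
    lo, hi = cfg.epoch_window_ms
    t = lo + dt * np.arange(int(round((hi - lo) / dt)) + 1)
    n, s = len(table), len(t)

    sign = np.where(table["cued_side"].to_numpy() == "right", 1.0, -1.0)
    deflect = np.exp(-0.5 * ((t - 500.0) / 250.0) ** 2)[None, :] * np.ones((n, 1))
    resp = (table["onset_ms"].to_numpy(float)
            + table["interrupter_rt_ms"].to_numpy(float))
    has = np.isfinite(resp)
    deflect[has] += np.exp(-0.5 * ((t[None, :] - resp[has, None] - 250.0) / 200.0) ** 2)
    x_common = towardness_amp * sign[:, None] * deflect \
        + _ou_noise(rng, (n, s), noise_sd, noise_tau_ms, dt)
    y_common = _ou_noise(rng, (n, s), noise_sd, noise_tau_ms, dt)

    eye_noise = lambda: _ou_noise(rng, (n, s), 0.05, 20.0, dt)
    x_l, x_r = x_common + eye_noise(), x_common + eye_noise()
    y_l, y_r = y_common + eye_noise(), y_common + eye_noise()

    blink_intervals = []
    duration_s = (hi - lo) / 1000.0
    for i in range(n):
        k = rng.poisson(blink_rate * duration_s)
        ivals = []
        for _ in range(k):
            b0 = rng.uniform(lo, hi - 300.0)
            b1 = b0 + rng.uniform(100.0, 300.0)
            mask = (t >= b0) & (t <= b1)
            for arr in (x_l, x_r, y_l, y_r):
                arr[i, mask] = blink_value
            ivals.append((float(b0), float(b1)))
        blink_intervals.append(ivals)

    return GazeRaw(x_left=x_l.astype(np.float32), x_right=x_r.astype(np.float32),
                   y_left=y_l.astype(np.float32), y_right=y_r.astype(np.float32),
                   times_ms=t, rate_hz=raw_rate_hz,
                   blink_intervals=blink_intervals,
                   table_index=table.index.to_numpy())


# ---------------------------------------------------------------------------
# EEG-like epochs

def _window_weight(t: np.ndarray, start: float, end: float,
                   ramp_ms: float = 100.0) -> np.ndarray:
    """Smooth 0→1→0 weight over [start, end] with raised-cosine ramps."""
    w = np.zeros_like(t)
    core = (t >= start + ramp_ms) & (t <= end - ramp_ms)
    w[core] = 1.0
    up = (t >= start) & (t < start + ramp_ms)
    w[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp_ms))
    down = (t > end - ramp_ms) & (t <= end)
    w[down] = 0.5 * (1 - np.cos(np.pi * (end - t[down]) / ramp_ms))
    if end - start < 2 * ramp_ms:  # short window: single raised-cosine bump
        mid = 0.5 * (start + end)
        inside = (t >= start) & (t <= end)
        w[:] = 0.0
        w[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - start) / (end - start)))
    return w


def _one_over_f(rng, n_trials, n_ch, n_samp, sd, dt_s):
    white = rng.standard_normal((n_trials, n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samp, d=dt_s)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n_samp, axis=-1)
    out *= sd / out.std(axis=-1, keepdims=True)
    return out


def sample_epochs(table: pd.DataFrame, cfg: TaskConfig,
                  effects: list[NeuralEffectSpec] | None = None,
                  noise_sd: float = 1.0,
                  channels: tuple = ("PO7", "PO8", "C3", "C4"),
                  participant_attenuation_sd: float = 0.08,
                  amplitude_cv: float = 0.2,
                  seed: int | None = None) -> EpochArray:
    """Epoched multichannel signals for the cohort in ``table``.

    Each channel carries 1/f background noise; channels named in an
    effect's pair additionally carry a band-limited oscillation whose
    contralateral amplitude is reduced by ``contra_attenuation`` inside the
    effect's windows (response-locked windows are placed at interrupter
    onset + the trial's simulated reaction time + ``motor_delay_ms``).
    Attenuation and oscillation amplitude vary across participants so
    group-level statistics face realistic between-subject variance.
    """
    if effects is None:
        effects = default_neural_effects()
    for eff in effects:
        for ch in eff.channel_pair:
            if ch not in channels:
                raise ValueError(f"effect channel {ch!r} not in channel set {channels}")
    base_seed = cfg.seed if seed is None else seed
    t = cfg.times_ms()
    dt_s = 1.0 / cfg.sampling_rate_hz
    pids = table["participant"].unique()
    n_trials = table.groupby("participant").size()
    if n_trials.nunique() != 1:
        raise ValueError("all participants must have the same trial count")
    n_tr = int(n_trials.iloc[0])

    data = np.empty((len(pids), n_tr, len(channels), len(t)), dtype=np.float32)
    for pi, pid in enumerate(pids):
        rng = _rng(base_seed, 4, int(pid))
        sub = table[table["participant"] == pid]
        x = _one_over_f(rng, n_tr, len(channels), len(t), noise_sd, dt_s)
        resp = (sub["onset_ms"].to_numpy(float)
                + sub["interrupter_rt_ms"].to_numpy(float))
        onset = sub["onset_ms"].to_numpy(float)
        for eff in effects:
            a_p = float(np.clip(rng.normal(eff.contra_attenuation,
                                           participant_attenuation_sd), 0.0, 0.95))
            amp_p = eff.osc_amplitude * rng.lognormal(0.0, amplitude_cv)
            feature = (sub["cued_side"] if eff.basis == "item-side"
                       else sub["response_hand"]).to_numpy()
            for ch in eff.channel_pair:
                ci = channels.index(ch)
                hemi = hemisphere(ch)
                contra = feature != hemi  # feature on opposite side → contra
                f_tr = rng.uniform(eff.band[0], eff.band[1], size=n_tr)
                phase = rng.uniform(0, 2 * np.pi, size=n_tr)
                amp_tr = amp_p * rng.lognormal(0.0, amplitude_cv, size=n_tr)
                osc = np.sin(2 * np.pi * f_tr[:, None] * (t[None, :] / 1000.0)
                             + phase[:, None])
                w = _trial_weights(t, eff, onset, resp, cfg)
                gain = 1.0 - a_p * w * contra[:, None]
                x[:, ci, :] += amp_tr[:, None] * gain * osc
        data[pi] = x
    return EpochArray(data=data, participants=np.asarray(pids),
                      channels=list(channels), sfreq=cfg.sampling_rate_hz,
                      times_ms=t, meta={"noise_sd": noise_sd})


def _trial_weights(t, eff: NeuralEffectSpec, onset, resp, cfg: TaskConfig):
    """(n_trials, n_times) attenuation-window weight, capped at 1."""
    n = len(onset)
    w = np.zeros((n, len(t)))
    epoch_end = cfg.epoch_window_ms[1]
    for win in eff.windows:
        if win.lock == "cue":
            s = np.full(n, win.start_ms)
            if win.end_ms is None:
                e = np.where(np.isfinite(onset), onset, epoch_end)
            else:
                e = np.full(n, win.end_ms)
            active = np.ones(n, bool)
        else:
            ev = resp + eff.motor_delay_ms
            active = np.isfinite(ev)
            s = ev + win.start_ms
            e = (np.full(n, np.inf) if win.end_ms is None else ev + win.end_ms)
            e = np.minimum(e, epoch_end)
        for i in np.flatnonzero(active):
            if e[i] > s[i]:
                w[i] += _window_weight(t, float(s[i]), float(min(e[i], epoch_end)))
    return np.minimum(w, 1.0)


# ---------------------------------------------------------------------------
# response-locked band courses (for lag analyses)

def sample_reselection_courses(n_participants: int = 20,
                               motor_delay_ms: float = 0.0,
                               sfreq: float = 250.0,
                               window_ms: tuple = (-400.0, 400.0),
                               amp: float = 1.0, peak_ms: float = 100.0,
                               width_ms: float = 60.0, noise_sd: float = 0.05,
                               noise_tau_ms: float = 60.0,
                               seed: int = 0):
    """Per-participant visual and motor reselection band courses.

    Both are negative-going (attenuation) bumps peaking ``peak_ms`` after
    the interrupter response; the motor course is delayed by
    ``motor_delay_ms``. These emulate *trial-averaged* participant-level
    band courses, so the residual noise level is low (``noise_sd`` is a
    fraction of the bump amplitude). Returns ``(times_ms, visual, motor)``
    with course arrays of shape (n_participants, n_times).
    """
    rng = _rng(seed, 5)
    dt = 1000.0 / sfreq
    t = window_ms[0] + dt * np.arange(int(round((window_ms[1] - window_ms[0]) / dt)) + 1)
    shape_v = -np.exp(-0.5 * ((t - peak_ms) / width_ms) ** 2)
    shape_m = -np.exp(-0.5 * ((t - peak_ms - motor_delay_ms) / width_ms) ** 2)
    amps = amp * rng.lognormal(0.0, 0.2, size=(n_participants, 2))
    visual = amps[:, :1] * shape_v + _ou_noise(rng, (n_participants, len(t)),
                                               noise_sd, noise_tau_ms, dt)
    motor = amps[:, 1:] * shape_m + _ou_noise(rng, (n_participants, len(t)),
                                              noise_sd, noise_tau_ms, dt)
    return t, visual, motor
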