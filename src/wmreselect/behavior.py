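"""Behavioral analysis of continuous orientation reports.

Covers trial exclusion, reproduction-error statistics against the 45°
chance level, maximum-likelihood decomposition of reports into
target / nontarget(swap) / guess components, and the moving-window
response-bias curve over the target–interrupter angular difference.

All circular computations run on doubled angles: orientations are
180°-periodic, so θ → 2θ maps them onto the full circle where the von
Mises distribution applies; the uniform (guess) component then has density
1/2π, and the chance-level mean absolute error is 45°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0e

from .circular import orientation_error, signed_orientation_diff, to_doubled_radians
from .containers import validate_trial_table
from .stats import TTestResult, one_sample_t, paired_t

__all__ = [
    "ExclusionConfig",
    "MixtureFit",
    "BiasCurve",
    "apply_exclusions",
    "fit_mixture",
    "response_bias_curve",
    "chance_and_condition_tests",
    "orientation_error",
]

CHANCE_ERROR_DEG = 45.0


@dataclass(frozen=True)
class ExclusionConfig:
    """Trial- and dataset-level exclusion rules."""

    rt_abs_max_ms: float = 5000.0
    rt_sd_mult: float = 2.5
    interrupter_deadline_ms: float = 800.0
    max_rejected_fraction: float = 0.15
    max_condition_error_deg: float = CHANCE_ERROR_DEG

    def __post_init__(self):
        for name in ("rt_abs_max_ms", "rt_sd_mult", "interrupter_deadline_ms",
                     "max_rejected_fraction", "max_condition_error_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def apply_exclusions(table: pd.DataFrame,
                     cfg: ExclusionConfig = ExclusionConfig()):
    """Remove bad trials and flag unusable datasets.

    Trials are removed when the probe RT exceeds ``rt_abs_max_ms`` or lies
    more than ``rt_sd_mult`` SD above the participant's mean (across all
    conditions), and — on interruption trials — when the interrupter
    response is missing, wrong, or slower than the deadline. Participants
    whose rejected fraction exceeds ``max_rejected_fraction``, or whose
    mean absolute error reaches ``max_condition_error_deg`` in any
    block-type × onset condition, are flagged (not silently dropped).

    Returns ``(filtered_table, report, flags)`` where ``report`` is a
    per-participant rejection summary and ``flags`` a per-participant
    boolean frame of dataset-level exclusion reasons.
    """
    validate_trial_table(table, require=("participant", "rt_probe_ms",
                                         "block_type", "interrupter_rt_ms",
                                         "interrupter_correct"))
    t = table.copy()
    rt = t["rt_probe_ms"].to_numpy(float)
    stats = t.groupby("participant")["rt_probe_ms"].agg(["mean", "std"])
    mean_p = t["participant"].map(stats["mean"]).to_numpy()
    sd_p = t["participant"].map(stats["std"]).to_numpy()
    bad_rt = (rt > cfg.rt_abs_max_ms) | (rt > mean_p + cfg.rt_sd_mult * sd_p)

    interrupted = t["block_type"].to_numpy() == "interruption"
    irt = t["interrupter_rt_ms"].to_numpy(float)
    icorrect = t["interrupter_correct"].to_numpy()
    bad_int = interrupted & (
        ~np.isfinite(irt) | (irt > cfg.interrupter_deadline_ms)
        | (icorrect != True)  # noqa: E712 — column may hold NaN
    )
    removed = bad_rt | bad_int

    report = pd.DataFrame({
        "n_trials": t.groupby("participant").size(),
        "n_removed": pd.Series(removed, index=t.index)
                       .groupby(t["participant"]).sum().astype(int),
    })
    report["fraction_removed"] = report["n_removed"] / report["n_trials"]

    kept = t[~removed]
    flags = pd.DataFrame(index=report.index)
    flags["too_many_rejected"] = report["fraction_removed"] > cfg.max_rejected_fraction
    cond_err = pd.Series(False, index=report.index)
    if kept["reported_orientation"].notna().any():
        err = orientation_error(kept["reported_orientation"], kept["target_orientation"])
        grouped = (pd.DataFrame({"participant": kept["participant"],
                                 "cond": kept["block_type"].astype(str) + "/"
                                         + kept["onset_condition"].astype(str),
                                 "err": err})
                   .groupby(["participant", "cond"])["err"].mean())
        worst = grouped.groupby("participant").max()
        cond_err = worst.reindex(report.index).fillna(0.0) >= cfg.max_condition_error_deg
    flags["at_chance_in_a_condition"] = cond_err
    flags["excluded"] = flags.any(axis=1)
    return kept, report, flags


# ---------------------------------------------------------------------------
# circular mixture model

@dataclass
class MixtureFit:
    """Three-component circular mixture estimate."""

    p_target: float
    p_nontarget: float
    p_guess: float
    kappa: float
    log_likelihood: float
    n_trials: int
    converged: bool = True
    boundary: bool = False

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p_target, self.p_nontarget, self.p_guess])


def _vm_logpdf(x, kappa):
    # log von Mises density at mean 0; i0e = exp(-k) I0(k) keeps large k finite
    return kappa * (np.cos(x) - 1.0) - np.log(2 * np.pi * i0e(kappa))


def _a1_inv(r: float) -> float:
    """Invert A(κ) = I1(κ)/I0(κ) = r (Fisher's piecewise approximation)."""
    r = min(max(r, 0.0), 1.0 - 1e-10)
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)

_KAPPA_MAX = 1e4
# identifiability floor: a von Mises with κ → 0 is indistinguishable from the
# uniform guess component, so the memory components are kept at least as
# concentrated as κ = 1 (≈ 29° report SD in orientation space)
_KAPPA_MIN = 1.0


def fit_mixture(errors_to_target, errors_to_nontarget,
                n_restarts: int = 10, tol: float = 1e-8,
                max_iter: int = 500, seed: int = 0) -> MixtureFit:
    """Maximum-likelihood three-component mixture fit by EM.

    Parameters are the proportions of reports centered on the target,
    centered on the nontarget (interrupter) — both von Mises with a shared
    concentration κ on doubled angles — and uniform guesses. Inputs are
    *signed* errors in orientation degrees (report − target and
    report − nontarget respectively), matched per trial.
    """
    et = to_doubled_radians(np.asarray(errors_to_target, float))
    en = to_doubled_radians(np.asarray(errors_to_nontarget, float))
    if et.shape != en.shape:
        raise ValueError("target and nontarget error lists must be matched per trial")
    n = et.size
    if n < 2:
        raise ValueError("need at least 2 trials")

    rng = np.random.default_rng(seed)
    log_u = -np.log(2 * np.pi)
    best = None
    # deterministic near-pure-target start plus random restarts
    starts = [(np.array([0.94, 0.03, 0.03]), 8.0)]
    for _ in range(n_restarts - 1):
        starts.append((rng.dirichlet([2.0, 1.0, 1.0]),
                       float(np.exp(rng.uniform(np.log(0.5), np.log(50.0))))))

    for p0, k0 in starts:
        p, kappa = p0.copy(), k0
        ll_old, converged = -np.inf, False
        for _ in range(max_iter):
            with np.errstate(over="ignore"):
                logd = np.stack([
                    np.log(p[0] + 1e-300) + _vm_logpdf(et, kappa),
                    np.log(p[1] + 1e-300) + _vm_logpdf(en, kappa),
                    np.full(n, np.log(p[2] + 1e-300) + log_u),
                ])
            mx = logd.max(axis=0)
            lse = mx + np.log(np.exp(logd - mx).sum(axis=0))
            ll = float(lse.sum())
            gamma = np.exp(logd - lse)
            p = gamma.sum(axis=1) / n
            wsum = gamma[0].sum() + gamma[1].sum()
            if wsum > 1e-12:
                rbar = float((gamma[0] @ np.cos(et) + gamma[1] @ np.cos(en)) / wsum)
                kappa = min(max(_a1_inv(rbar), _KAPPA_MIN), _KAPPA_MAX)
            if ll - ll_old < tol * max(1.0, abs(ll)) and ll >= ll_old:
                converged = True
                break
            ll_old = ll
        if best is None or ll > best[0]:
            best = (ll, p, kappa, converged)

    ll, p, kappa, converged = best
    return MixtureFit(p_target=float(p[0]), p_nontarget=float(p[1]),
                      p_guess=float(p[2]), kappa=float(kappa),
                      log_likelihood=ll, n_trials=n, converged=converged,
                      boundary=kappa >= _KAPPA_MAX)


# ---------------------------------------------------------------------------
# response-bias curve

@dataclass
class BiasCurve:
    """Moving-window response-bias curve.

    ``bias`` holds the per-participant matrix (participants × bins) of mean
    demeaned signed errors; empty bins are NaN, never 0. Sign convention:
    positive differences and biases are anticlockwise. An attractive bias
    toward the interrupter shows as bias sharing the sign of the
    target–interrupter difference.
    """

    bin_centers: np.ndarray
    bias: np.ndarray
    participants: np.ndarray
    step: float = 5.0
    width: float = 45.0

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.bias, axis=0)


def response_bias_curve(table: pd.DataFrame, step: float = 5.0,
                        width: float = 45.0) -> BiasCurve:
    """Response bias as a function of the target–interrupter difference.

    Signed errors (report − target) are demeaned per participant across all
    interruption trials (removing constant response bias), then binned by
    the signed interrupter − target difference with a moving window
    (default step 5°, width 45°) on the 180°-periodic difference axis.
    """
    rows = table[np.isfinite(table["interrupter_orientation"].to_numpy(float))
                 & table["reported_orientation"].notna()]
    if len(rows) == 0:
        raise ValueError("no interruption trials with reports")
    err = signed_orientation_diff(rows["reported_orientation"],
                                  rows["target_orientation"])
    diff = signed_orientation_diff(rows["interrupter_orientation"],
                                   rows["target_orientation"])
    pid = rows["participant"].to_numpy()
    participants = np.unique(pid)
    centers = np.arange(-90.0, 90.0 + step / 2, step)
    bias = np.full((len(participants), len(centers)), np.nan)
    for i, p in enumerate(participants):
        sel = pid == p
        e = err[sel] - err[sel].mean()
        d = diff[sel]
        for j, c in enumerate(centers):
            # wrap-aware distance on the 180°-periodic difference axis
            dist = np.abs(signed_orientation_diff(d, c))
            inside = dist <= width / 2
            if inside.any():
                bias[i, j] = e[inside].mean()
    return BiasCurve(bin_centers=centers, bias=bias, participants=participants,
                     step=step, width=width)


# ---------------------------------------------------------------------------
# group-level tests

def participant_mean_errors(table: pd.DataFrame) -> pd.DataFrame:
    """Participant × block-type mean absolute reproduction errors."""
    err = orientation_error(table["reported_orientation"],
                            table["target_orientation"])
    return (pd.DataFrame({"participant": table["participant"],
                          "block_type": table["block_type"], "error": err})
            .groupby(["participant", "block_type"])["error"].mean()
            .unstack("block_type"))


def chance_and_condition_tests(errors_by_condition: pd.DataFrame) -> dict:
    """Chance-level and between-condition tests on participant means.

    Expects a participants × conditions frame of mean absolute errors
    (e.g. from :func:`participant_mean_errors`). Runs a one-sample t
    against the 45° chance level per condition and, when both block types
    are present, a paired t between no-interruption and interruption, with
    Cohen's d on difference scores.
    """
    if len(errors_by_condition) < 2:
        raise ValueError("need at least 2 participants")
    out: dict[str, TTestResult] = {}
    for cond in errors_by_condition.columns:
        vals = errors_by_condition[cond].dropna().to_numpy()
        out[f"{cond}_vs_chance"] = one_sample_t(vals, CHANCE_ERROR_DEG)
    if {"no-interruption", "interruption"} <= set(errors_by_condition.columns):
        both = errors_by_condition[["no-interruption", "interruption"]].dropna()
        out["interruption_vs_no_interruption"] = paired_t(
            both["interruption"], both["no-interruption"])
    return out
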