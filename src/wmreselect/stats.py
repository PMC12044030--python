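"""Nonparametric inference: cluster-based sign-flip permutation tests,
generalized extreme studentized deviate (ESD) outlier rejection, and the
t-test/effect-size helpers used throughout.

The cluster test controls the family-wise error over a 1-D course
(participants × time) or a 2-D map (participants × frequency × time):
pointwise one-sample t-values against zero are thresholded at the two-sided
critical value for ``cluster_alpha``; contiguous supra-threshold points
(4-neighborhood in 2-D) form clusters whose mass is the summed t; the null
distribution of the maximum |mass| is built by randomly flipping the sign
of whole participants, and each observed cluster is assigned
p = (1 + #{null ≥ mass}) / (1 + n_permutations). With few participants the
sign-flip group is enumerated exhaustively instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sp_stats

__all__ = [
    "Cluster",
    "ClusterResult",
    "TTestResult",
    "cluster_permutation_test",
    "paired_cluster_test",
    "esd_reject",
    "one_sample_t",
    "paired_t",
]

_STRUCTURE_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-neighborhood


@dataclass
class Cluster:
    """One contiguous supra-threshold region."""

    indices: tuple  # tuple of index arrays, one per data dimension
    mass: float  # summed t-values (signed)
    p: float
    sign: int  # +1 positive cluster, −1 negative

    @property
    def start(self) -> int:
        """First index along the last (time) axis."""
        return int(np.min(self.indices[-1]))

    @property
    def stop(self) -> int:
        """Last index along the last (time) axis (inclusive)."""
        return int(np.max(self.indices[-1]))


@dataclass
class ClusterResult:
    clusters: list
    t_obs: np.ndarray
    threshold: float
    n_permutations: int
    cluster_alpha: float
    sided: str = "two"
    exhaustive: bool = False
    zero_variance: bool = False
    null_max_mass: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p < alpha]

    def to_dict(self, times=None, freqs=None) -> dict:
        """JSON-serializable report; index ranges in axis units if given."""
        out = {"n_permutations": self.n_permutations,
               "cluster_alpha": self.cluster_alpha, "sided": self.sided,
               "exhaustive": self.exhaustive, "clusters": []}
        for c in self.clusters:
            d = {"mass": float(c.mass), "p": float(c.p), "sign": int(c.sign),
                 "start_index": c.start, "stop_index": c.stop}
            if times is not None:
                d["start_ms"] = float(times[c.start])
                d["stop_ms"] = float(times[c.stop])
            if freqs is not None and len(c.indices) == 2:
                d["freq_range_hz"] = [float(freqs[int(np.min(c.indices[0]))]),
                                      float(freqs[int(np.max(c.indices[0]))])]
            out["clusters"].append(d)
        return out


# stand-in t for zero-variance points with nonzero mean (exact constant
# effects in synthetic data); zero-variance zero-mean points get t = 0
_T_DEGENERATE = 1e15


def _t_map(data: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t against 0 over the participant axis (axis 0)."""
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)),
                     np.sign(m) * _T_DEGENERATE)
    return t


def _cluster_masses(t: np.ndarray, threshold: float):
    """Clusters of strictly supra-threshold points, separately per sign.
    Returns (list of (indices, mass, sign), max |mass|)."""
    structure = _STRUCTURE_2D if t.ndim == 2 else np.ones(3)
    found, max_mass = [], 0.0
    for sign in (1, -1):
        mask = (sign * t) > threshold
        if not mask.any():
            continue
        labels, n_lab = ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            idx = np.nonzero(labels == lab)
            mass = float(t[idx].sum())
            found.append((idx, mass, sign))
            max_mass = max(max_mass, abs(mass))
    return found, max_mass


def _sign_matrix(n_subj: int, n_perm: int, rng, exhaustive: bool):
    if exhaustive:
        bits = np.arange(2**n_subj)
        return np.where((bits[:, None] >> np.arange(n_subj)) & 1, 1.0, -1.0)
    return rng.choice([-1.0, 1.0], size=(n_perm, n_subj))


def cluster_permutation_test(data: np.ndarray, n_permutations: int = 1024,
                             cluster_alpha: float = 0.05, sided: str = "two",
                             seed: int = 0, min_participants: int = 5,
                             exhaustive: bool | None = None) -> ClusterResult:
    """One-sample cluster permutation test of ``data`` against zero.

    Parameters
    ----------
    data : (n_participants, n_times) or (n_participants, n_freqs, n_times)
    exhaustive : enumerate all 2**n sign patterns instead of sampling;
        defaults to automatic when 2**n ≤ n_permutations.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim not in (2, 3):
        raise ValueError("data must be 2-D or 3-D with participants first")
    n = data.shape[0]
    if n < min_participants:
        raise ValueError(f"need at least {min_participants} participants, got {n}")
    if np.isnan(data).any():
        raise ValueError("missing values inside the tested region")
    if sided != "two":
        raise ValueError("only the two-sided test is implemented")

    zero_var = bool(np.all(data.std(axis=0) == 0))
    threshold = float(sp_stats.t.ppf(1 - cluster_alpha / 2, df=n - 1))

    if exhaustive is None:
        exhaustive = 2**n <= n_permutations
    rng = np.random.default_rng(seed)
    signs = _sign_matrix(n, n_permutations, rng, exhaustive)
    n_eff = signs.shape[0]

    # Sign flips leave per-point mean-of-squares unchanged, so the flipped
    # t-map needs only the flipped mean: t = m / sqrt((q − m²)/(n−1)).
    # The observed map goes through the identical arithmetic (identity
    # pattern) so exhaustive enumeration counts it exactly.
    flat = data.reshape(n, -1)
    q = (flat**2).mean(axis=0)
    shape = data.shape[1:]

    def flipped_t(sign_row):
        m = sign_row @ flat / n
        with np.errstate(divide="ignore", invalid="ignore"):
            var = np.maximum(q - m**2, 0.0) * n / (n - 1)
            t = np.where(var > 0, m / np.sqrt(var / n),
                         np.sign(m) * _T_DEGENERATE)
        return t.reshape(shape)

    t_obs = flipped_t(np.ones(n))
    observed, _ = _cluster_masses(t_obs, threshold)

    null_max = np.empty(n_eff)
    for i in range(n_eff):
        _, null_max[i] = _cluster_masses(flipped_t(signs[i]), threshold)

    clusters = []
    for idx, mass, sign in observed:
        if exhaustive:
            p = float(np.mean(null_max >= abs(mass)))
        else:
            p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_eff)
        clusters.append(Cluster(indices=idx, mass=mass, p=float(p), sign=sign))
    clusters.sort(key=lambda c: c.start)
    return ClusterResult(clusters=clusters, t_obs=t_obs, threshold=threshold,
                         n_permutations=n_eff, cluster_alpha=cluster_alpha,
                         sided=sided, exhaustive=exhaustive,
                         zero_variance=zero_var, null_max_mass=null_max)


def paired_cluster_test(a: np.ndarray, b: np.ndarray, **kwargs) -> ClusterResult:
    """Paired-condition cluster test: one-sample test on a − b."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"condition shapes differ: {a.shape} vs {b.shape}")
    return cluster_permutation_test(a - b, **kwargs)


# ---------------------------------------------------------------------------
# generalized ESD

def esd_reject(trial_scores, max_outliers: int, alpha: float = 0.05) -> np.ndarray:
    """Generalized (Rosner) ESD test: indices of detected outliers.

    Iteratively removes the most extreme studentized value; after computing
    all ``max_outliers`` test statistics R_i and critical values λ_i, flags
    the largest i for which R_i > λ_i (handles masking by design).
    """
    x = np.asarray(trial_scores, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trial scores must be finite")
    n = x.size
    if max_outliers >= n / 2:
        raise ValueError("max_outliers must be < n/2")
    if n < 4:
        raise ValueError("too few observations for the ESD test")

    remaining = np.arange(n)
    removed, r_stats, lambdas = [], [], []
    for i in range(1, max_outliers + 1):
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        r_stats.append(dev[j] / sd)
        m = n - i + 1  # observations entering this round
        p = 1 - alpha / (2 * m)
        tcrit = sp_stats.t.ppf(p, df=m - 2)
        lambdas.append((m - 1) * tcrit / np.sqrt((m - 2 + tcrit**2) * m))
        removed.append(remaining[j])
        remaining = np.delete(remaining, j)

    n_out = 0
    for i in range(len(r_stats), 0, -1):
        if r_stats[i - 1] > lambdas[i - 1]:
            n_out = i
            break
    return np.sort(np.asarray(removed[:n_out], dtype=int))


# ---------------------------------------------------------------------------
# t-tests with effect sizes

@dataclass
class TTestResult:
    t: float
    p: float
    d: float  # Cohen's d (difference scores for the paired case)
    df: int
    mean: float
    zero_variance: bool = False


def one_sample_t(values, popmean: float = 0.0) -> TTestResult:
    """One-sample t-test with Cohen's d = (mean − popmean) / sd."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    diff = x.mean() - popmean
    if sd == 0:
        return TTestResult(t=np.inf * np.sign(diff) if diff else 0.0,
                           p=0.0 if diff else 1.0,
                           d=np.inf * np.sign(diff) if diff else 0.0,
                           df=x.size - 1, mean=float(x.mean()),
                           zero_variance=True)
    res = sp_stats.ttest_1samp(x, popmean)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       d=float(diff / sd), df=x.size - 1, mean=float(x.mean()))


def paired_t(a, b) -> TTestResult:
    """Paired t-test; d is computed on the difference scores."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal shapes")
    return one_sample_t(a - b, 0.0)
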