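"""Method-comparison statistics: Passing–Bablok, cusum, Bland–Altman, Spearman.

Passing–Bablok regression estimates the slope as the shifted median of all
pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i): slopes of exactly -1 are
excluded, and the median index is offset by K, the number of slopes below
-1, which makes the estimator invariant to swapping the two methods.
Confidence intervals use the rank-based normal approximation of the
original procedure.  The companion cusum test checks linearity: residual
signs, weighted to a zero-sum walk and accumulated in x-order, form a
tied-down random walk whose scaled maximum excursion is referred to the
Kolmogorov–Smirnov distribution.

Bland–Altman agreement reports the mean difference (bias) and the 95%
limits of agreement bias ± 1.96·sd; note these are limits of agreement, not
a confidence interval of the bias (the bias CI is also provided).  Spearman
rank correlation uses average ranks for ties, a Fisher-z confidence
interval, and a t-approximation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "PairedSample",
    "PassingBablokResult",
    "BlandAltmanResult",
    "SpearmanResult",
    "MetricAgreement",
    "passing_bablok",
    "cusum_linearity",
    "bland_altman",
    "spearman_ci",
    "compare_methods",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements (standard, two-short) for one metric."""

    x: np.ndarray             # standard protocol
    y: np.ndarray             # two-short protocol
    metric: str = ""
    labels: tuple = ()

    def __post_init__(self):
        x = np.asarray(self.x, float)
        y = np.asarray(self.y, float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1D arrays")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class PassingBablokResult:
    intercept: float
    slope: float
    intercept_ci: tuple
    slope_ci: tuple
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    lower_limit: float
    upper_limit: float
    sd: float
    bias_ci: tuple
    n: int


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci: tuple
    p_value: float
    n: int


@dataclass(frozen=True)
class MetricAgreement:
    """One row of the method-comparison report (one metric)."""

    metric: str
    pb: PassingBablokResult
    cusum_p: float
    ba: BlandAltmanResult
    spearman: SpearmanResult


def _pairwise_slopes(x: np.ndarray, y: np.ndarray):
    """All defined pairwise slopes; ties in x with distinct y give ±inf."""
    n = x.size
    slopes = []
    for i in range(n - 1):
        dx = x[i + 1:] - x[i]
        dy = y[i + 1:] - y[i]
        for a, b in zip(dx, dy):
            if a == 0.0:
                if b == 0.0:
                    continue            # identical points: slope undefined
                slopes.append(np.inf if b > 0 else -np.inf)
            else:
                slopes.append(b / a)
    return np.array(slopes)


def passing_bablok(s: PairedSample, ci_level: float = 0.95) -> PassingBablokResult:
    """Passing–Bablok regression with rank-based confidence intervals."""
    x, y = s.x, s.y
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]):
        raise ValueError("all x equal; slope undefined")
    slopes = _pairwise_slopes(x, y)
    slopes = slopes[slopes != -1.0]     # exclude slopes of exactly -1
    if slopes.size == 0:
        raise ValueError("no defined pairwise slopes")
    slopes = np.sort(slopes)
    N = slopes.size
    K = int(np.sum(slopes < -1.0))

    # shifted median (1-indexed ranks, clamped at the boundaries for the
    # degenerate case of very many slopes below -1)
    def at(rank):
        return slopes[min(max(rank, 1), N) - 1]

    if N % 2 == 1:
        b = at((N + 1) // 2 + K)
    else:
        b = 0.5 * (at(N // 2 + K) + at(N // 2 + 1 + K))

    z = stats.norm.ppf(0.5 + ci_level / 2)
    c = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((N - c) / 2.0))
    m2 = N - m1 + 1
    lo = slopes[max(m1 + K - 1, 0)] if 1 <= m1 + K <= N else -np.inf
    hi = slopes[min(m2 + K - 1, N - 1)] if 1 <= m2 + K <= N else np.inf

    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - hi * x)) if np.isfinite(hi) else -np.inf
    a_hi = float(np.median(y - lo * x)) if np.isfinite(lo) else np.inf
    return PassingBablokResult(a, float(b), (a_lo, a_hi), (float(lo), float(hi)), n)


def cusum_linearity(s: PairedSample, fit: PassingBablokResult,
                    n_permutations: int = 2000) -> float:
    """Cusum linearity test p-value for a Passing–Bablok fit.

    Residual signs are weighted to a zero-sum walk (scores +sqrt(L/l) and
    -sqrt(l/L) for the l positive and L negative residuals) and accumulated
    in order of increasing x; the test statistic is the maximum excursion of
    that tied-down walk, whose asymptotic reference is the
    Kolmogorov–Smirnov distribution.  The p-value is evaluated against the
    exact conditional null — random orderings of the observed scores,
    enumerated by Monte-Carlo with a fixed internal seed — because the KS
    asymptote is noticeably conservative at the sample sizes of a
    method-comparison study.  Exactly linear data (all residuals zero)
    returns p = 1.
    """
    r = s.y - fit.intercept - fit.slope * s.x
    tol = 1e-12 * max(1.0, float(np.max(np.abs(s.y))) if len(s) else 1.0)
    pos = r > tol
    neg = r < -tol
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        return 1.0
    scores = np.zeros(len(s))
    scores[pos] = np.sqrt(n_neg / n_pos)
    scores[neg] = -np.sqrt(n_pos / n_neg)
    order = np.argsort(s.x, kind="stable")
    m_obs = float(np.max(np.abs(np.cumsum(scores[order]))))

    rng = np.random.default_rng(1906)   # fixed: p-values are deterministic
    perms = rng.permuted(np.tile(scores, (n_permutations, 1)), axis=1)
    m_null = np.max(np.abs(np.cumsum(perms, axis=1)), axis=1)
    p = (1 + int(np.sum(m_null >= m_obs - 1e-12))) / (1 + n_permutations)
    return float(min(p, 1.0))


def cusum_statistic_ks_pvalue(m_obs: float, n: int) -> float:
    """Asymptotic (Kolmogorov–Smirnov) p-value of the cusum excursion."""
    return float(special.kolmogorov(m_obs / np.sqrt(n)))


def bland_altman(s: PairedSample, ci_level: float = 0.95) -> BlandAltmanResult:
    """Bias and limits of agreement of differences d = two_short - standard."""
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = s.y - s.x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    # the conventional 1.96 multiplier, as printed in method-comparison
    # reports, rather than the full-precision normal quantile
    z = 1.96 if ci_level == 0.95 else stats.norm.ppf(0.5 + ci_level / 2)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, n - 1)
    return BlandAltmanResult(bias, bias - z * sd, bias + z * sd, sd,
                             (bias - tcrit * se, bias + tcrit * se), n)


def spearman_ci(s: PairedSample, ci_level: float = 0.95) -> SpearmanResult:
    """Spearman rank correlation with Fisher-z CI and t-approximation p."""
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = stats.rankdata(s.x)
    ry = stats.rankdata(s.y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("zero rank variance; rho undefined")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.sum(rx * ry) / np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))

    if abs(rho) >= 1.0:
        p = 0.0
        ci = (rho, rho)
    else:
        tstat = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        p = float(2 * stats.t.sf(abs(tstat), n - 2))
        if n > 3:
            zr = np.arctanh(rho)
            zse = 1.0 / np.sqrt(n - 3)
            zc = stats.norm.ppf(0.5 + ci_level / 2)
            ci = (float(np.tanh(zr - zc * zse)), float(np.tanh(zr + zc * zse)))
        else:
            ci = (np.nan, np.nan)
    return SpearmanResult(rho, ci, p, n)


def compare_methods(s: PairedSample, ci_level: float = 0.95) -> MetricAgreement:
    """The full battery for one metric: PB + cusum, BA, Spearman."""
    pb = passing_bablok(s, ci_level)
    return MetricAgreement(
        metric=s.metric,
        pb=pb,
        cusum_p=cusum_linearity(s, pb),
        ba=bland_altman(s, ci_level),
        spearman=spearman_ci(s, ci_level),
    )
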