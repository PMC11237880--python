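"""Shared paired-comparison engine: paired t, Cohen's d and their CIs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq


@dataclass
class PairedResult:
    """Paired t-test summary for one comparison (difference = a - b)."""

    mean_diff: float
    t: float
    df: int
    p: float
    p_adjusted: float
    ci_low: float
    ci_high: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    n: int

    def as_dict(self) -> dict:
        return {
            "difference": self.mean_diff, "t": self.t, "df": self.df,
            "p": self.p, "p_adjusted": self.p_adjusted,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "cohens_d": self.cohens_d,
            "d_ci_low": self.d_ci_low, "d_ci_high": self.d_ci_high,
            "n": self.n,
        }


def bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def _d_confint(t_obs: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """CI for Cohen's d of paired data by noncentral-t inversion.

    Finds the noncentrality deltas whose nct distribution places the
    observed t at the (1 +/- level)/2 quantiles; d bounds are delta/sqrt(n).
    """
    df = n - 1
    alpha = 1.0 - level
    span = abs(t_obs) + 10.0 + 10.0 / max(np.sqrt(n), 1.0)

    def cdf(nc: float) -> float:
        v = stats.nct.cdf(t_obs, df, nc)
        if np.isnan(v):  # scipy underflows for extreme noncentrality
            return 0.0 if nc > t_obs else 1.0
        return float(v)

    def solve(q: float) -> float:
        f = lambda nc: cdf(nc) - q
        lo, hi = t_obs - span, t_obs + span
        # widen until bracketing (cdf is monotone decreasing in nc)
        while f(lo) < 0:
            lo -= span
        while f(hi) > 0:
            hi += span
        return brentq(f, lo, hi, xtol=1e-8)

    nc_hi = solve(alpha / 2.0)     # upper bound
    nc_lo = solve(1.0 - alpha / 2.0)
    rt = np.sqrt(n)
    return nc_lo / rt, nc_hi / rt


def paired_ttest(a: np.ndarray, b: np.ndarray, m_comparisons: int = 1,
                 level: float = 0.95) -> PairedResult:
    """Two-sided paired t-test of a vs b with effect-size summaries.

    Cohen's d is the mean difference over the SD of the differences
    (ddof = 1); its CI comes from noncentral-t inversion. The adjusted p
    is the Bonferroni value min(1, p * m_comparisons).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    mean = d.mean()
    se = sd / np.sqrt(n)
    t_obs = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_obs), df)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    cohens_d = mean / sd
    d_lo, d_hi = _d_confint(t_obs, n, level)
    return PairedResult(
        mean_diff=float(mean), t=float(t_obs), df=int(df), p=float(p),
        p_adjusted=bonferroni(p, m_comparisons),
        ci_low=float(mean - tcrit * se), ci_high=float(mean + tcrit * se),
        cohens_d=float(cohens_d), d_ci_low=float(d_lo), d_ci_high=float(d_hi),
        n=int(n),
    )
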