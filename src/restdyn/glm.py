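"""Haemodynamic GLM mapping of state (or alpha-power) time courses.

State probability courses are convolved with the canonical double-gamma
haemodynamic response function, sampled onto the TR grid and used as
explanatory variables in per-run ordinary-least-squares GLMs with positive
and negative mean-activation contrasts. Run-level betas are averaged into
per-subject condition maps (fixed effects) and taken to the group with
one-sample or paired t-tests, Bonferroni-corrected across targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class HRFKernel:
    """Sampled double-gamma haemodynamic impulse response, peak-normalized."""

    times: np.ndarray
    values: np.ndarray
    step: float
    peak_delay: float
    undershoot_delay: float
    ratio: float

    @property
    def duration(self) -> float:
        return self.times[-1] + self.step


def double_gamma_hrf(step: float, peak_delay: float = 6.0,
                     undershoot_delay: float = 16.0, ratio: float = 1.0 / 6.0,
                     length: float = 32.0) -> HRFKernel:
    """Canonical double-gamma HRF on a grid of ``step`` seconds.

    h(t) = g(t; shape=peak_delay) - ratio * g(t; shape=undershoot_delay),
    both unit-scale gamma densities, normalized to peak height 1. With the
    default parameters the response peaks near 5 s (the mode of a gamma
    density with shape 6 is 5, perturbed <0.1 s by the undershoot),
    h(0) = 0, and a late negative undershoot spans roughly 10-30 s.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if length <= undershoot_delay:
        raise ValueError("kernel length must exceed the undershoot delay")
    if peak_delay <= 1 or undershoot_delay <= 1:
        raise ValueError("gamma shapes must exceed 1 for a zero-onset response")
    t = np.arange(0.0, length, step)
    h = stats.gamma.pdf(t, a=peak_delay) - ratio * stats.gamma.pdf(t, a=undershoot_delay)
    h = h / h.max()
    return HRFKernel(times=t, values=h, step=step, peak_delay=peak_delay,
                     undershoot_delay=undershoot_delay, ratio=ratio)


def build_regressor(course: np.ndarray, rate: float, tr: float = 2.0,
                    hrf: HRFKernel | None = None,
                    n_out: int | None = None) -> np.ndarray:
    """HRF-convolve a native-rate course and sample it on the TR grid.

    Causal same-length convolution with zero pre-history at the course's
    native rate, then evaluation at the TR instants t = 0, TR, 2 TR, ...
    ``n_out`` defaults to floor(duration / TR) and must match the paired
    fMRI run's length.
    """
    course = np.asarray(course, float)
    if course.ndim != 1:
        raise ValueError("course must be 1-D")
    if rate < 1.0 / tr:
        raise ValueError("course rate must be at least the TR rate")
    hrf = hrf or double_gamma_hrf(step=1.0 / rate)
    if hrf.values.size > course.size:
        raise ValueError("HRF kernel longer than the run")
    conv = np.convolve(course, hrf.values)[: course.size]
    if n_out is None:
        n_out = int(np.floor(course.size / (tr * rate)))
    idx = np.floor(np.arange(n_out) * tr * rate).astype(int)
    if idx.size and idx[-1] >= course.size:
        raise ValueError(
            f"requested {n_out} TR samples but the course only spans "
            f"{course.size / rate:g} s"
        )
    return conv[idx]


@dataclass
class GlmResult:
    """Per-target OLS estimates with +/- contrast t-maps."""

    betas: np.ndarray          # (V, P) one column per regressor (no intercept)
    t: np.ndarray              # (V, P)
    df: int
    sigma2: np.ndarray         # (V,) unbiased residual variance
    level: str                 # "first" | "subject" | "group"

    @property
    def t_positive(self) -> np.ndarray:
        return self.t

    @property
    def t_negative(self) -> np.ndarray:
        return -self.t


def first_level_glm(Y: np.ndarray, X: np.ndarray,
                    prewhiten_ar1: bool = False) -> GlmResult:
    """OLS of each target series on the regressors plus an intercept.

    ``Y`` is targets x time, ``X`` time x regressors (intercept added
    internally; regressors demeaned first). Rank deficiency raises and
    names the collinear columns. ``prewhiten_ar1=True`` estimates a single
    AR(1) coefficient from pooled residuals and refits on the whitened
    model.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    T, P = X.shape
    if Y.shape[1] != T:
        raise ValueError(f"time mismatch: Y has {Y.shape[1]} samples, X has {T}")
    Xd = X - X.mean(axis=0)
    design = np.column_stack([np.ones(T), Xd])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by dropping each in turn
        bad = [
            j for j in range(1, design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear regressor columns {bad}")
    if T <= design.shape[1]:
        raise ValueError("need more time points than design columns")

    def _fit(Yf: np.ndarray, Df: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pinv = np.linalg.pinv(Df)
        coef = Yf @ pinv.T                      # (V, P+1)
        resid = Yf - coef @ Df.T
        dof = Df.shape[0] - Df.shape[1]
        sigma2 = (resid ** 2).sum(axis=1) / dof
        xtx_inv = np.linalg.inv(Df.T @ Df)
        se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, coef / se, 0.0)
        return coef, tval, sigma2

    coef, tval, sigma2 = _fit(Y, design)
    if prewhiten_ar1:
        resid = Y - coef @ design.T
        r = resid[:, :-1].ravel()
        r1 = resid[:, 1:].ravel()
        denom = float(r @ r)
        rho = float(r @ r1 / denom) if denom > 0 else 0.0
        rho = float(np.clip(rho, -0.99, 0.99))
        Yw = Y[:, 1:] - rho * Y[:, :-1]
        Dw = design[1:] - rho * design[:-1]
        coef, tval, sigma2 = _fit(Yw, Dw)
        T_eff = Yw.shape[1]
        return GlmResult(betas=coef[:, 1:], t=tval[:, 1:],
                         df=T_eff - design.shape[1], sigma2=sigma2, level="first")
    return GlmResult(betas=coef[:, 1:], t=tval[:, 1:],
                     df=T - design.shape[1], sigma2=sigma2, level="first")


def subject_level_average(run_results: list[GlmResult],
                          conditions: list[str]) -> dict[str, np.ndarray]:
    """Fixed-effects average of run betas per condition for one subject."""
    if len(run_results) != len(conditions):
        raise ValueError("one condition label per run result required")
    out: dict[str, list[np.ndarray]] = {}
    for res, cond in zip(run_results, conditions):
        out.setdefault(cond, []).append(res.betas)
    for cond in ("EO", "EC"):
        if cond in out and not out[cond]:
            raise ValueError(f"no runs for condition {cond}")
    return {cond: np.mean(np.stack(b), axis=0) for cond, b in out.items()}


@dataclass
class GroupResult:
    """Group-level t-map over targets with Bonferroni-adjusted p-values."""

    t: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray
    df: int
    contrast: str
    significant: np.ndarray    # Bonferroni-adjusted p < alpha
    alpha: float


def group_level_test(subject_maps: dict[str, np.ndarray] | np.ndarray,
                     contrast: str = "EO", alpha: float = 0.05) -> GroupResult:
    """One-sample (or paired, for EO-EC style contrasts) group t-map.

    ``subject_maps`` is either a (subjects, targets) array for a plain
    one-sample test, or a {"EO": (N, V), "EC": (N, V)} dict from which the
    contrast selects a condition mean ("EO", "EC") or a paired difference
    ("EO-EC", "EC-EO"). Zero-variance targets are flagged missing (NaN).
    """
    if isinstance(subject_maps, dict):
        if contrast in ("EO", "EC"):
            data = np.asarray(subject_maps[contrast], float)
        elif contrast in ("EO-EC", "EC-EO"):
            a, b = contrast.split("-")
            data = np.asarray(subject_maps[a], float) - np.asarray(subject_maps[b], float)
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
    else:
        data = np.asarray(subject_maps, float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError("need a (subjects >= 3, targets) matrix")
    n, V = data.shape
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    t = np.full(V, np.nan)
    p = np.full(V, np.nan)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), n - 1)
    p_adj = np.where(np.isnan(p), np.nan, np.minimum(1.0, p * V))
    sig = np.zeros(V, dtype=bool)
    sig[ok] = p_adj[ok] < alpha
    return GroupResult(t=t, p=p, p_adjusted=p_adj, df=n - 1,
                       contrast=contrast, significant=sig, alpha=alpha)
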