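"""Sliding-window fractional occupancy and cross-modal correlation.

Fractional occupancy computed inside a sliding window (default 10 s,
zero overlap) turns each run's state path into a windows x states time
course; averaging these across subjects exposes slow trends such as the
post-eye-closure occupancy spike. Because windows are defined in seconds
from run start, an EEG-state course (computed on a 25 ms or 40 Hz grid)
and an fMRI-state course (TR grid) of the same run share one window grid
and can be correlated cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._stats import bonferroni
from .hmm import ViterbiPath
from .metrics import fractional_occupancy


@dataclass
class WindowFOCourse:
    """Windows x states fractional-occupancy matrix for one run or group."""

    values: np.ndarray            # (W, K), rows sum to 1
    window_length: float          # seconds
    overlap: float                # seconds
    level: str                    # "run-subject" | "group-mean"
    condition: str = ""
    subject: str = ""
    run_index: int = 0
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_states(self) -> int:
        return self.values.shape[1]


def windowed_fo(path: ViterbiPath, window_length: float = 10.0,
                overlap: float = 0.0) -> WindowFOCourse:
    """Fractional occupancy inside each sliding window of a decoded run.

    Window w covers samples [w*step, w*step + width); a trailing partial
    window is dropped, so with zero overlap the windows exactly tile the
    analysed span (width * n_windows samples).
    """
    period = path.sampling_period
    if window_length < period:
        raise ValueError("window shorter than one sample")
    if overlap >= window_length:
        raise ValueError("overlap must be smaller than the window length")
    width = int(round(window_length / period))
    step = width - int(round(overlap / period))
    if step < 1:
        raise ValueError("window step must be at least one sample")
    T = len(path)
    n_win = (T - width) // step + 1
    if n_win < 1:
        raise ValueError("run shorter than one window")
    values = np.empty((n_win, path.n_states))
    for w in range(n_win):
        seg = path.states[w * step: w * step + width]
        values[w] = fractional_occupancy(seg, path.n_states)
    return WindowFOCourse(
        values=values, window_length=window_length, overlap=overlap,
        level="run-subject", condition=path.condition, subject=path.subject,
        run_index=path.run_index,
    )


def group_average_fo(courses: Sequence[WindowFOCourse],
                     level: float = 0.95) -> WindowFOCourse:
    """Pointwise mean course across subjects with a t-based CI band.

    All courses must be aligned on an identical window grid (same window
    length, overlap and count). CI = mean +/- t(n-1, (1+level)/2) * SE;
    degenerate (zero-SE) windows get a zero-width band.
    """
    if not courses:
        raise ValueError("no courses to average")
    ref = courses[0]
    for c in courses[1:]:
        if (c.values.shape != ref.values.shape
                or c.window_length != ref.window_length
                or c.overlap != ref.overlap):
            raise ValueError("window grids are not aligned across subjects")
    stack = np.stack([c.values for c in courses])      # (n, W, K)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n > 1:
        se = stack.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    else:
        se = np.zeros_like(mean)
        tcrit = 0.0
    return WindowFOCourse(
        values=mean, window_length=ref.window_length, overlap=ref.overlap,
        level="group-mean", condition=ref.condition, run_index=ref.run_index,
        ci_low=mean - tcrit * se, ci_high=mean + tcrit * se,
    )


@dataclass
class CrossModalMatrix:
    """Pearson correlations between two models' windowed-FO courses."""

    r: np.ndarray            # (K_a, K_b); NaN where a course had no variance
    p: np.ndarray
    p_adjusted: np.ndarray   # Bonferroni over all cells
    n_windows: int
    run_index: int = 0
    condition: str = ""

    @property
    def m_comparisons(self) -> int:
        return self.r.size


def crossmodal_correlation(course_a: WindowFOCourse, course_b: WindowFOCourse,
                           m_comparisons: int | None = None) -> CrossModalMatrix:
    """Correlate every state pair of two same-run windowed-FO courses.

    r[i, j] is the Pearson correlation over windows between state i of
    course_a and state j of course_b; two-sided p-values come from the t
    transform and are Bonferroni-adjusted over all cells (m defaults to
    K_a * K_b; e.g. 6 fMRI x 5 EEG states gives m = 30). Zero-variance
    courses yield NaN cells reported as missing.
    """
    if course_a.n_windows != course_b.n_windows:
        raise ValueError(
            f"window grids differ: {course_a.n_windows} vs {course_b.n_windows}"
        )
    W = course_a.n_windows
    if W < 3:
        raise ValueError("need at least 3 windows to correlate")
    Ka, Kb = course_a.n_states, course_b.n_states
    if m_comparisons is None:
        m_comparisons = Ka * Kb
    r = np.full((Ka, Kb), np.nan)
    p = np.full((Ka, Kb), np.nan)
    sd_a = course_a.values.std(axis=0)
    sd_b = course_b.values.std(axis=0)
    for i in range(Ka):
        for j in range(Kb):
            if sd_a[i] == 0 or sd_b[j] == 0:
                continue
            res = stats.pearsonr(course_a.values[:, i], course_b.values[:, j])
            r[i, j], p[i, j] = res.statistic, res.pvalue
    p_adj = np.where(np.isnan(p), np.nan,
                     np.minimum(1.0, p * m_comparisons))
    return CrossModalMatrix(
        r=r, p=p, p_adjusted=p_adj, n_windows=W,
        run_index=course_a.run_index, condition=course_a.condition,
    )


def gamma_windowed_fo(gamma: np.ndarray, sampling_period: float,
                      window_length: float = 10.0, overlap: float = 0.0,
                      **labels) -> WindowFOCourse:
    """Probability-weighted alternative to Viterbi windowed occupancy:
    mean gamma inside each window."""
    if window_length < sampling_period:
        raise ValueError("window shorter than one sample")
    width = int(round(window_length / sampling_period))
    step = width - int(round(overlap / sampling_period))
    if step < 1:
        raise ValueError("window step must be at least one sample")
    T, K = gamma.shape
    n_win = (T - width) // step + 1
    if n_win < 1:
        raise ValueError("run shorter than one window")
    values = np.stack([
        gamma[w * step: w * step + width].mean(axis=0) for w in range(n_win)
    ])
    return WindowFOCourse(values=values, window_length=window_length,
                          overlap=overlap, level="run-subject", **labels)
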