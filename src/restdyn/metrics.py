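"""Viterbi-path state metrics and EO-vs-EC paired contrasts.

Metrics per run: fractional occupancy (share of samples each state
occupies), state lifetimes (duration of each visit), interval times (gaps
between consecutive visits of the same state) and the switching rate
(state changes per sample, with a per-second convenience). Condition
contrasts are paired t-tests over subject-level means with Bonferroni
correction; lifetimes and intervals are reported descriptively only, since
visit counts differ between conditions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import PairedResult, paired_ttest
from .hmm import ViterbiPath


def fractional_occupancy(path: ViterbiPath | np.ndarray, n_states: int | None = None
                         ) -> np.ndarray:
    """Per-state share of samples; sums to 1 over states."""
    states = path.states if isinstance(path, ViterbiPath) else np.asarray(path, int)
    if states.size == 0:
        raise ValueError("empty path")
    K = n_states if n_states is not None else (
        path.n_states if isinstance(path, ViterbiPath) else int(states.max()) + 1)
    return np.bincount(states, minlength=K) / states.size


def _visits(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encoding: (state, start, length) per maximal constant run."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return states[starts], starts, ends - starts


def lifetimes(path: ViterbiPath | np.ndarray, sampling_period: float | None = None,
              n_states: int | None = None,
              include_truncated: bool = True) -> list[np.ndarray]:
    """Per-state visit durations in seconds, one entry per maximal visit.

    Visits truncated by the run boundary (the first and last visit) are
    counted by default; ``include_truncated=False`` drops them.
    """
    if isinstance(path, ViterbiPath):
        states, period, K = path.states, path.sampling_period, path.n_states
    else:
        states = np.asarray(path, int)
        period = sampling_period
        K = n_states if n_states is not None else int(states.max()) + 1
    if period is None or period <= 0:
        raise ValueError("sampling_period must be positive")
    vstates, _, vlens = _visits(states)
    if not include_truncated and vstates.size:
        keep = np.ones(vstates.size, dtype=bool)
        keep[0] = keep[-1] = False
        vstates, vlens = vstates[keep], vlens[keep]
    return [vlens[vstates == k] * period for k in range(K)]


def interval_times(path: ViterbiPath | np.ndarray,
                   sampling_period: float | None = None,
                   n_states: int | None = None) -> list[np.ndarray]:
    """Gaps between consecutive visits of each state, in seconds.

    States visited fewer than twice yield empty lists.
    """
    if isinstance(path, ViterbiPath):
        states, period, K = path.states, path.sampling_period, path.n_states
    else:
        states = np.asarray(path, int)
        period = sampling_period
        K = n_states if n_states is not None else int(states.max()) + 1
    if period is None or period <= 0:
        raise ValueError("sampling_period must be positive")
    vstates, starts, vlens = _visits(states)
    out = []
    for k in range(K):
        idx = np.flatnonzero(vstates == k)
        if idx.size < 2:
            out.append(np.empty(0))
            continue
        gap_samples = starts[idx[1:]] - (starts[idx[:-1]] + vlens[idx[:-1]])
        out.append(gap_samples * period)
    return out


def switching_rate(path: ViterbiPath | np.ndarray) -> float:
    """State changes per sample: transitions / (T - 1)."""
    states = path.states if isinstance(path, ViterbiPath) else np.asarray(path, int)
    if states.size < 2:
        raise ValueError("switching rate needs at least 2 samples")
    return float(np.count_nonzero(np.diff(states)) / (states.size - 1))


def restrict_first_quarter(paths: Sequence[ViterbiPath]) -> list[ViterbiPath]:
    """Keep only the first floor(T/4) samples of each path.

    For a 300-sample run at TR 2 s this is 75 samples = 2.5 min.
    """
    out = []
    for p in paths:
        if len(p) < 4:
            raise ValueError(f"run {(p.subject, p.run_index)} too short to quarter")
        out.append(ViterbiPath(
            states=p.states[: len(p) // 4],
            sampling_period=p.sampling_period, n_states=p.n_states,
            subject=p.subject, run_index=p.run_index, condition=p.condition,
        ))
    return out


def state_metrics_table(paths: Sequence[ViterbiPath]) -> pd.DataFrame:
    """Long-format table of per-(subject, run, state) metrics.

    Columns: subject, run_index, condition, state, fractional_occupancy,
    mean_lifetime, mean_interval, n_visits plus the per-run switching rate
    (repeated across the run's state rows) in per-sample and per-second
    units. Lifetime/interval means are NaN for unvisited states.
    """
    rows = []
    for p in paths:
        fo = fractional_occupancy(p)
        lt = lifetimes(p)
        iv = interval_times(p)
        sr = switching_rate(p)
        for k in range(p.n_states):
            rows.append({
                "subject": p.subject,
                "run_index": p.run_index,
                "condition": p.condition,
                "state": k,
                "fractional_occupancy": fo[k],
                "mean_lifetime": float(np.mean(lt[k])) if lt[k].size else np.nan,
                "n_visits": int(lt[k].size),
                "mean_interval": float(np.mean(iv[k])) if iv[k].size else np.nan,
                "switching_rate": sr,
                "switching_rate_per_s": sr / p.sampling_period,
            })
    return pd.DataFrame(rows)


def compare_conditions(table: pd.DataFrame, metric: str = "fractional_occupancy",
                       m_comparisons: int | None = None) -> pd.DataFrame:
    """Paired EO-vs-EC t-tests on subject-level means of a state metric.

    Same-condition runs are averaged within subject before pairing, so the
    test has df = n_subjects - 1. For ``fractional_occupancy`` one test per
    state is run (Bonferroni m defaults to the state count); for
    ``switching_rate`` a single test is run. The difference is EO - EC.
    Returns one row per comparison, mirroring a
    difference / t / p / adjusted p / CI / Cohen's d table layout.
    """
    if metric not in ("fractional_occupancy", "switching_rate"):
        raise ValueError("metric must be fractional_occupancy or switching_rate")
    per_state = metric == "fractional_occupancy"
    states = sorted(table["state"].unique()) if per_state else [None]
    if m_comparisons is None:
        m_comparisons = len(states)
    results = []
    for k in states:
        sub = table if k is None else table[table["state"] == k]
        # within-subject mean over same-condition runs
        pivot = sub.pivot_table(index="subject", columns="condition",
                                values=metric, aggfunc="mean")
        if not {"EO", "EC"}.issubset(pivot.columns) or pivot[["EO", "EC"]].isna().any().any():
            raise ValueError("every subject needs at least one run per condition")
        res: PairedResult = paired_ttest(
            pivot["EO"].to_numpy(), pivot["EC"].to_numpy(),
            m_comparisons=m_comparisons,
        )
        row = {"state": k if k is not None else -1, "metric": metric}
        row.update(res.as_dict())
        results.append(row)
    return pd.DataFrame(results)
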