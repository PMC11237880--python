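"""Model selection: state-number scan, repeat reliability, max occupancy.

The inference is stochastic (seed-dependent initialization) and does not
itself choose the number of states, so models are refit over a range of
state counts with several repeats each. Three diagnostics guide the
choice: variational free energy (lower = better fit, but decreases with
every added state, so never used alone), per-run maximum fractional
occupancy (high values mean one state dominates a run - a dynamics-poor
model), and repeat reliability (mean correlation of assignment-matched
state probability courses across repeats). The decision rule keeps the
largest state number whose mean reliability clears a floor (default 0.80)
and, within it, the repeat with the lowest mean per-run max occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .data import Dataset, subseed
from .hmm import HMMSpec, TrainedHMM, ViterbiPath, decode_dataset, fit_vb
from .metrics import fractional_occupancy


def repeat_reliability(gammas_a: Sequence[np.ndarray],
                       gammas_b: Sequence[np.ndarray]
                       ) -> tuple[list[tuple[int, int]], float]:
    """Match two fits' states and return the mean matched correlation.

    State probability courses are concatenated over runs; states are
    paired one-to-one by maximizing total Pearson correlation (optimal
    linear assignment). A zero-variance course contributes r = 0 with a
    warning. Returns (matched index pairs, mean matched r).
    """
    a = np.concatenate(list(gammas_a), axis=0)
    b = np.concatenate(list(gammas_b), axis=0)
    if a.shape != b.shape:
        raise ValueError("gamma sets must share run structure and state count")
    K = a.shape[1]
    r = np.zeros((K, K))
    sd_a, sd_b = a.std(axis=0), b.std(axis=0)
    if np.any(sd_a == 0) or np.any(sd_b == 0):
        warnings.warn("zero-variance state course; its correlations set to 0")
    for i in range(K):
        for j in range(K):
            if sd_a[i] == 0 or sd_b[j] == 0:
                continue
            r[i, j] = np.corrcoef(a[:, i], b[:, j])[0, 1]
    rows, cols = linear_sum_assignment(-r)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    return pairs, float(r[rows, cols].mean())


def max_fractional_occupancy(paths: Sequence[ViterbiPath],
                             n_states: int | None = None) -> np.ndarray:
    """Per run, the largest single-state occupancy (in (0, 1])."""
    return np.array([
        fractional_occupancy(p, n_states).max() for p in paths
    ])


@dataclass
class SelectionReport:
    """Everything the decision rule needs, per (state count, repeat)."""

    entries: pd.DataFrame                 # k, repeat, free_energy, mean_max_fo, ok
    reliability: dict[int, np.ndarray]    # per k: repeats x repeats mean matched r
    mean_reliability: dict[int, float]
    models: dict[tuple[int, int], TrainedHMM] = field(default_factory=dict)
    chosen: tuple[int, int] | None = None
    rationale: str = ""

    def model(self, k: int, repeat: int) -> TrainedHMM:
        return self.models[(k, repeat)]

    @property
    def chosen_model(self) -> TrainedHMM:
        if self.chosen is None:
            raise ValueError("no model chosen yet; run select_model")
        return self.models[self.chosen]


def scan_states(dataset: Dataset, k_range: Sequence[int] = range(2, 16),
                repeats: int = 5, base_seed: int = 0,
                spec_kwargs: dict | None = None,
                keep_models: bool = True) -> SelectionReport:
    """Fit (len(k_range) x repeats) models and collect selection metrics.

    Every fit's seed derives deterministically from ``base_seed`` and its
    (k, repeat) cell, so the scan is reproducible and any cell can be
    refit in isolation. A single failed fit is recorded (ok = False), not
    fatal; a state count with fewer than 2 successful repeats is flagged
    in its reliability entry (NaN).
    """
    spec_kwargs = dict(spec_kwargs or {})
    rows = []
    models: dict[tuple[int, int], TrainedHMM] = {}
    paths_cache: dict[tuple[int, int], list[ViterbiPath]] = {}
    for k in k_range:
        for rep in range(repeats):
            seed = subseed(base_seed, k, rep)
            try:
                model = fit_vb(dataset, HMMSpec(n_states=k, seed=seed, **spec_kwargs))
                paths = decode_dataset(model, dataset)
                paths_cache[(k, rep)] = paths
                models[(k, rep)] = model
                rows.append({
                    "k": k, "repeat": rep, "seed": seed, "ok": True,
                    "free_energy": model.free_energy_final,
                    "mean_max_fo": float(max_fractional_occupancy(paths, k).mean()),
                })
            except Exception as err:  # recorded, not fatal
                warnings.warn(f"fit failed for k={k} repeat={rep}: {err}")
                rows.append({
                    "k": k, "repeat": rep, "seed": seed, "ok": False,
                    "free_energy": np.nan, "mean_max_fo": np.nan,
                })
    entries = pd.DataFrame(rows)

    reliability: dict[int, np.ndarray] = {}
    mean_reliability: dict[int, float] = {}
    for k in k_range:
        good = [rep for rep in range(repeats) if (k, rep) in models]
        mat = np.full((repeats, repeats), np.nan)
        np.fill_diagonal(mat, 1.0)
        if len(good) >= 2:
            for i_idx, i in enumerate(good):
                for j in good[i_idx + 1:]:
                    _, r = repeat_reliability(models[(k, i)].gamma,
                                              models[(k, j)].gamma)
                    mat[i, j] = mat[j, i] = r
            off = mat[np.triu_indices(repeats, 1)]
            mean_reliability[k] = float(np.nanmean(off))
        else:
            warnings.warn(f"k={k}: fewer than 2 successful repeats")
            mean_reliability[k] = np.nan
        reliability[k] = mat

    return SelectionReport(
        entries=entries, reliability=reliability,
        mean_reliability=mean_reliability,
        models=models if keep_models else {},
    )


def select_model(report: SelectionReport, reliability_floor: float = 0.8,
                 fallback: bool = False) -> tuple[int, int]:
    """Apply the decision rule; returns and records (k, repeat).

    k = the largest state count whose mean repeat reliability meets the
    floor; repeat = the successful repeat at that k with the lowest mean
    per-run maximum fractional occupancy. If no state count clears the
    floor, the default is to raise; ``fallback=True`` instead takes the
    most reliable state count and says so in the rationale.
    """
    eligible = [k for k, r in report.mean_reliability.items()
                if np.isfinite(r) and r >= reliability_floor]
    note = ""
    if not eligible:
        best = max(
            (k for k in report.mean_reliability if np.isfinite(report.mean_reliability[k])),
            key=lambda k: report.mean_reliability[k], default=None)
        if not fallback or best is None:
            raise ValueError(
                f"no state count reaches reliability floor {reliability_floor}; "
                f"best available: k={best} "
                f"(r={report.mean_reliability.get(best, float('nan')):.3f})"
            )
        eligible = [best]
        note = (f" [fallback: no state count reached the floor "
                f"{reliability_floor}; most reliable taken]")
    k = max(eligible)
    sub = report.entries[(report.entries["k"] == k) & report.entries["ok"]]
    row = sub.loc[sub["mean_max_fo"].idxmin()]
    rep = int(row["repeat"])
    report.chosen = (k, rep)
    report.rationale = (
        f"k={k}: largest state count with mean repeat reliability "
        f"{report.mean_reliability[k]:.3f} >= floor {reliability_floor}; "
        f"repeat {rep} has the lowest mean max fractional occupancy "
        f"({row['mean_max_fo']:.3f})" + note
    )
    return k, rep
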