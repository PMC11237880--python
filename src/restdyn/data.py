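"""Run-level data containers and plain-text I/O.

A study is a collection of labelled runs: one ``RunSeries`` per
(subject, run) holding a time x channel matrix together with its sampling
period, behavioural condition (eyes-open ``"EO"`` or eyes-closed ``"EC"``),
and modality tag. Runs are written as TSV matrices (header row of channel
labels) and described by a JSON manifest so a study round-trips through
plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("EO", "EC")

#: posterior electrodes used for the alpha analysis
EEG_CHANNELS = ("Oz", "O1", "O2", "POz", "PO3", "PO4")

#: 13 resting-state network labels for the fMRI-like series
FMRI_CHANNELS = (
    "vis_occ_pole", "vis_medial", "vis_lateral", "auditory", "dan",
    "dmn_ant", "dmn_post", "precuneus", "salience", "smn_superior",
    "smn_inferior", "fpn_left", "fpn_right",
)


@dataclass
class RunSeries:
    """One run's multichannel time series with its acquisition labels."""

    data: np.ndarray                # (T, C) float64
    sampling_period: float          # seconds between samples
    condition: str                  # "EO" | "EC"
    subject: str
    run_index: int                  # position in the session (0-based)
    modality: str                   # "fmri" | "eeg" | derived tags
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be a 2-D time x channel matrix")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not self.channels:
            self.channels = tuple(f"ch{i}" for i in range(self.data.shape[1]))
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel labels do not match data columns")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.sampling_period

    @property
    def duration(self) -> float:
        """Run duration in seconds (samples x sampling period)."""
        return self.n_samples * self.sampling_period

    def key(self) -> tuple[str, int]:
        return (self.subject, self.run_index)

    def with_data(self, data: np.ndarray) -> "RunSeries":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class Dataset:
    """Ordered collection of runs sharing one modality and channel set."""

    runs: list[RunSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.runs:
            c = self.runs[0].n_channels
            for r in self.runs:
                if r.n_channels != c:
                    raise ValueError(
                        f"run {r.key()} has {r.n_channels} channels, expected {c}"
                    )

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)

    def __getitem__(self, i) -> RunSeries:
        return self.runs[i]

    @property
    def n_channels(self) -> int:
        if not self.runs:
            raise ValueError("empty dataset")
        return self.runs[0].n_channels

    def concatenated(self) -> np.ndarray:
        """All runs stacked along time, in dataset order."""
        return np.concatenate([r.data for r in self.runs], axis=0)

    def run_lengths(self) -> np.ndarray:
        return np.array([r.n_samples for r in self.runs], dtype=int)

    def subjects(self) -> list[str]:
        out: list[str] = []
        for r in self.runs:
            if r.subject not in out:
                out.append(r.subject)
        return out


# ---------------------------------------------------------------------------
# plain-text serialization


def write_run_tsv(run: RunSeries, path: str | Path) -> None:
    df = pd.DataFrame(run.data, columns=list(run.channels))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_run_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), tuple(df.columns)


def save_dataset(dataset: Dataset, out_dir: str | Path,
                 manifest_name: str = "manifest.json") -> Path:
    """Write every run as TSV plus a JSON manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for run in dataset:
        fname = f"{run.modality}_sub-{run.subject}_run-{run.run_index:02d}.tsv"
        write_run_tsv(run, out / fname)
        entries.append({
            "file": fname,
            "subject": run.subject,
            "run_index": run.run_index,
            "condition": run.condition,
            "modality": run.modality,
            "sampling_period": run.sampling_period,
            "n_samples": run.n_samples,
            "channels": list(run.channels),
        })
    manifest = {"runs": entries}
    mpath = out / manifest_name
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load a dataset from a JSON manifest, validating shapes and labels.

    Raises a specific error naming the offending run for a missing file,
    a row/column count that disagrees with the manifest, or an unknown
    condition label.
    """
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    base = mpath.parent
    runs = []
    for e in manifest["runs"]:
        f = base / e["file"]
        if not f.exists():
            raise FileNotFoundError(f"run file missing: {f} (subject {e['subject']})")
        if e["condition"] not in CONDITIONS:
            raise ValueError(
                f"unknown condition {e['condition']!r} for subject "
                f"{e['subject']} run {e['run_index']}"
            )
        data, channels = read_run_tsv(f)
        if data.shape != (e["n_samples"], len(e["channels"])):
            raise ValueError(
                f"shape mismatch for {f.name}: file has {data.shape}, manifest "
                f"says ({e['n_samples']}, {len(e['channels'])})"
            )
        runs.append(RunSeries(
            data=data,
            sampling_period=float(e["sampling_period"]),
            condition=e["condition"],
            subject=str(e["subject"]),
            run_index=int(e["run_index"]),
            modality=e["modality"],
            channels=tuple(channels),
        ))
    return Dataset(runs)


def subseed(seed: int, *key: int) -> int:
    """Derive a child seed (< 2**31) from a study seed and an integer key path.

    All randomness in the package flows from one seed through this
    derivation, so any single run can be regenerated without simulating
    the runs before it.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
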