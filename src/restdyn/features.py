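"""EEG alpha-band feature extraction.

The posterior alpha pipeline: bandpass 7-13 Hz (zero-phase), Hilbert
envelope for the HMM inputs, TR epoching with downsampling to 40 Hz,
per-epoch Welch alpha power averaged over the posterior channel set
(Oz, O1/2, PO3/4, POz), z-scored per run for use as a GLM regressor, and
the subject-level EO-vs-EC paired alpha-power test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._stats import PairedResult, paired_ttest
from .data import Dataset, RunSeries

ALPHA_BAND = (7.0, 13.0)
POSTERIOR_CHANNELS = ("Oz", "O1", "O2", "PO3", "PO4", "POz")


def bandpass_alpha(run: RunSeries, low: float = ALPHA_BAND[0],
                   high: float = ALPHA_BAND[1], order: int = 4) -> RunSeries:
    """Zero-phase Butterworth bandpass (applied forward-backward)."""
    if run.rate <= 2.0 * high:
        raise ValueError(
            f"sampling rate {run.rate:g} Hz too low for a {high:g} Hz band edge"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=run.rate,
                     output="sos")
    return run.with_data(sps.sosfiltfilt(sos, run.data, axis=0))


def hilbert_envelope(run: RunSeries) -> RunSeries:
    """Magnitude of the analytic signal, per channel.

    The first and last 0.5 s are edge-contaminated; ``envelope_edge_mask``
    flags them.
    """
    if not np.all(np.isfinite(run.data)):
        raise ValueError("non-finite samples in input")
    env = np.abs(sps.hilbert(run.data, axis=0))
    return replace(run, data=env, modality=run.modality + "-envelope")


def envelope_edge_mask(n_samples: int, rate: float,
                       edge_seconds: float = 0.5) -> np.ndarray:
    """Boolean mask, True on edge samples (first/last ``edge_seconds``)."""
    mask = np.zeros(n_samples, dtype=bool)
    k = min(n_samples, int(round(edge_seconds * rate)))
    mask[:k] = True
    mask[n_samples - k:] = True
    return mask


def epoch_and_downsample(run: RunSeries, tr: float = 2.0,
                         target_rate: float = 40.0
                         ) -> tuple[np.ndarray, RunSeries]:
    """Downsample to ``target_rate`` and cut into TR epochs.

    Integer decimation uses a polyphase anti-aliasing resample; a
    non-integer ratio falls back to rational polyphase resampling. Returns
    (epochs, downsampled run) where epochs has shape
    (n_epochs, tr * target_rate, C) and epochs tile the downsampled
    series exactly (concatenating them reconstructs it, up to the dropped
    remainder).
    """
    if run.duration < tr:
        raise ValueError("run shorter than one TR")
    ratio = run.rate / target_rate
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        data = run.data if q == 1 else sps.resample_poly(run.data, 1, q, axis=0)
    else:
        from fractions import Fraction
        frac = Fraction(target_rate / run.rate).limit_denominator(1000)
        data = sps.resample_poly(run.data, frac.numerator, frac.denominator, axis=0)
    ds = RunSeries(
        data=data, sampling_period=1.0 / target_rate, condition=run.condition,
        subject=run.subject, run_index=run.run_index,
        modality=run.modality + "-ds", channels=run.channels,
    )
    per_epoch = int(round(tr * target_rate))
    n_epochs = data.shape[0] // per_epoch
    epochs = data[: n_epochs * per_epoch].reshape(n_epochs, per_epoch, -1)
    return epochs, ds


def welch_alpha_power(epochs: np.ndarray, rate: float,
                      channels: tuple[str, ...],
                      band: tuple[float, float] = ALPHA_BAND,
                      use_channels: tuple[str, ...] = POSTERIOR_CHANNELS,
                      segment_seconds: float = 1.0) -> np.ndarray:
    """Channel-averaged Welch band power per epoch.

    Welch settings: Hann window, segments of ``segment_seconds`` with 50%
    overlap; the periodogram (a density) is summed over the band times the
    bin width, so a unit-amplitude in-band tone yields ~ its power
    a^2 / 2 = 0.5.
    """
    for ch in use_channels:
        if ch not in channels:
            raise ValueError(f"missing channel {ch!r} in input")
    idx = [channels.index(ch) for ch in use_channels]
    nperseg = min(epochs.shape[1], int(round(segment_seconds * rate)))
    f, psd = sps.welch(epochs[:, :, idx], fs=rate, window="hann",
                       nperseg=nperseg, noverlap=nperseg // 2, axis=1)
    df = f[1] - f[0]
    in_band = (f >= band[0]) & (f <= band[1])
    return psd[:, in_band, :].sum(axis=1).mean(axis=1) * df


@dataclass
class AlphaPowerCourse:
    """One channel-averaged alpha-power value per TR epoch of a run."""

    values: np.ndarray
    tr: float
    condition: str
    subject: str
    run_index: int
    channels: tuple[str, ...]
    normalized: bool = False

    def __len__(self) -> int:
        return self.values.size


def alpha_power_course(run: RunSeries, tr: float = 2.0,
                       target_rate: float = 40.0,
                       band: tuple[float, float] = ALPHA_BAND,
                       use_channels: tuple[str, ...] = POSTERIOR_CHANNELS,
                       prefiltered: bool = False) -> AlphaPowerCourse:
    """Full run-level alpha course: bandpass -> epoch -> Welch -> average."""
    filtered = run if prefiltered else bandpass_alpha(run, *band)
    epochs, _ = epoch_and_downsample(filtered, tr=tr, target_rate=target_rate)
    power = welch_alpha_power(epochs, target_rate, filtered.channels,
                              band=band, use_channels=use_channels)
    return AlphaPowerCourse(
        values=power, tr=tr, condition=run.condition, subject=run.subject,
        run_index=run.run_index, channels=use_channels,
    )


def normalize_regressor(course: AlphaPowerCourse) -> AlphaPowerCourse:
    """Z-score a run's power course (mean 0, SD 1); affine-invariant up to
    the sign of the scaling."""
    v = course.values
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance alpha course; cannot normalize")
    return replace(course, values=(v - v.mean()) / sd, normalized=True)


def envelope_dataset(runs: Dataset, band: tuple[float, float] = ALPHA_BAND,
                     target_rate: float = 40.0, tr: float = 2.0) -> Dataset:
    """HMM-ready envelope inputs: bandpass, downsample, Hilbert envelope.

    The output grid is ``target_rate`` and each run is truncated to whole
    TR epochs so its duration matches the paired fMRI run.
    """
    out = []
    for run in runs:
        filtered = bandpass_alpha(run, *band)
        _, ds = epoch_and_downsample(filtered, tr=tr, target_rate=target_rate)
        per_epoch = int(round(tr * target_rate))
        n = (ds.n_samples // per_epoch) * per_epoch
        env = hilbert_envelope(ds.with_data(ds.data[:n]))
        out.append(env)
    return Dataset(out)


def alpha_condition_test(courses: list[AlphaPowerCourse],
                         m_comparisons: int = 1) -> PairedResult:
    """Paired t-test of subject-mean EO vs EC alpha power.

    Each subject's EO (EC) value is the mean over all of their EO (EC)
    epochs; difference = EO - EC, df = n_subjects - 1.
    """
    rows = [{
        "subject": c.subject, "condition": c.condition,
        "power": float(c.values.mean()), "n": len(c),
    } for c in courses]
    df = pd.DataFrame(rows)
    agg = df.groupby(["subject", "condition"]).apply(
        lambda g: np.average(g["power"], weights=g["n"]), include_groups=False
    ).unstack()
    if not {"EO", "EC"}.issubset(agg.columns) or agg[["EO", "EC"]].isna().any().any():
        raise ValueError("every subject needs both conditions")
    return paired_ttest(agg["EO"].to_numpy(), agg["EC"].to_numpy(),
                        m_comparisons=m_comparisons)
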