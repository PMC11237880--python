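"""Synthetic eyes-open / eyes-closed study generator with known ground truth.

Emulates the study design the pipeline targets: 18-21 subjects, four
resting runs per subject in the order EO, EC, EO, EC; fMRI-like 13-channel
network time series on a TR = 2 s grid with 300 samples per run; EEG-like
6-channel posterior alpha oscillations at a raw rate of 200 Hz; and
parcel-level BOLD matrices driven by the state course through a
double-gamma haemodynamic response.

One latent Markov chain per run is sampled on the finest grid (the EEG raw
rate) and index-decimated to the TR grid, so both modalities share state
occupancy by construction. Condition effects enter through the chain's
stationary occupancy (an EC occupancy shift toward the high-alpha state,
optionally with a post-eye-closure spike decaying over ~2.5 min) and
through an EC alpha-amplitude scaling. All randomness derives from a single
study seed via documented per-run child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from ._kernels import ar1_noise, sample_chain, sample_chain_mixture
from .data import (
    Dataset, EEG_CHANNELS, FMRI_CHANNELS, RunSeries, subseed,
)
from .hmm import ViterbiPath


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class GroundTruth:
    """Generative parameters plus the realized per-run latent chains."""

    n_states: int
    transition_by_condition: dict[str, np.ndarray]
    initial_dist: np.ndarray
    state_means: np.ndarray                       # (K, C_fmri)
    state_covs: np.ndarray                        # (K, C, C), SPD
    state_alpha_amplitudes: np.ndarray            # (K, C_eeg), >= 0
    chain_paths: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    chain_rate: float = 200.0                     # Hz of the stored chains
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, a in self.transition_by_condition.items():
            a = np.asarray(a, float)
            if np.max(np.abs(a.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"{cond} transition rows must sum to 1")
            self.transition_by_condition[cond] = a
        if abs(float(np.sum(self.initial_dist)) - 1.0) > 1e-12:
            raise ValueError("initial_dist must sum to 1")
        for k, cov in enumerate(np.asarray(self.state_covs)):
            if np.min(np.linalg.eigvalsh(cov)) <= 0:
                raise ValueError(f"state {k} covariance is not positive definite")
        for path in self.chain_paths.values():
            if path.size and path.max() >= self.n_states:
                raise ValueError("chain path contains a state >= n_states")

    def chain_at(self, key: tuple[str, int], period: float) -> np.ndarray:
        """The stored chain index-decimated to a coarser sampling period."""
        chain = self.chain_paths[key]
        step = period * self.chain_rate
        idx = np.floor(np.arange(int(len(chain) / step)) * step).astype(int)
        return chain[idx]


@dataclass
class StudyManifest:
    """Study layout: who was scanned, in what order, on which grids."""

    subjects: tuple[str, ...] = tuple(f"s{i:02d}" for i in range(1, 22))
    runs_per_subject: tuple[str, ...] = ("EO", "EC", "EO", "EC")
    fmri_sampling_period: float = 2.0
    fmri_samples_per_run: int = 300
    eeg_raw_rate: float = 200.0
    eeg_channels: tuple[str, ...] = EEG_CHANNELS
    fmri_channels: tuple[str, ...] = FMRI_CHANNELS

    def __post_init__(self) -> None:
        if self.fmri_sampling_period <= 0 or self.eeg_raw_rate <= 0:
            raise ValueError("sampling periods must be positive")
        for c in self.runs_per_subject:
            if c not in ("EO", "EC"):
                raise ValueError(f"unknown condition {c!r}")

    @property
    def run_duration(self) -> float:
        return self.fmri_samples_per_run * self.fmri_sampling_period

    @property
    def eeg_samples_per_run(self) -> int:
        return int(round(self.run_duration * self.eeg_raw_rate))

    def to_dict(self) -> dict:
        return {
            "subjects": list(self.subjects),
            "runs_per_subject": list(self.runs_per_subject),
            "fmri_sampling_period": self.fmri_sampling_period,
            "fmri_samples_per_run": self.fmri_samples_per_run,
            "eeg_raw_rate": self.eeg_raw_rate,
            "eeg_channels": list(self.eeg_channels),
            "fmri_channels": list(self.fmri_channels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyManifest":
        d = dict(d)
        for k in ("subjects", "runs_per_subject", "eeg_channels", "fmri_channels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class EffectProfile:
    """How the EC condition differs from EO in the generator.

    ``stationary_*`` are the chains' target occupancies per condition;
    the high-alpha state is by convention the last one. ``dwell_seconds``
    sets the persistence timescale (mean visit length before a redraw).
    ``ramp_boost``/``ramp_tau_s`` add a post-eye-closure occupancy spike on
    the high-alpha state that decays exponentially (None disables it).
    """

    name: str = "paperlike"
    stationary_eo: np.ndarray = field(
        default_factory=lambda: np.array([0.30, 0.30, 0.25, 0.15]))
    stationary_ec: np.ndarray = field(
        default_factory=lambda: np.array([0.22, 0.23, 0.25, 0.30]))
    dwell_seconds: float = 6.0
    ec_amp_scale: float = 1.5
    ramp_boost: float | None = 0.5
    ramp_tau_s: float = 75.0
    fmri_mean_scale: float = 1.5
    eeg_noise_sd: float = 0.5
    eeg_carrier_hz: float = 10.0
    pink_noise: bool = False
    n_parcels: int = 40
    parcel_beta: float = 0.8
    parcel_ar1: float = 0.3
    parcel_noise_sd: float = 0.5

    @property
    def n_states(self) -> int:
        return len(self.stationary_eo)


def null_profile() -> EffectProfile:
    """No condition effect at all: EC chains and amplitudes match EO."""
    p = EffectProfile(name="null", ec_amp_scale=1.0, ramp_boost=None)
    return replace(p, stationary_ec=p.stationary_eo.copy())


def paperlike_profile() -> EffectProfile:
    return EffectProfile()


# ---------------------------------------------------------------------------
# elementary simulators


def mixture_transition(stationary: np.ndarray, persistence: float) -> np.ndarray:
    """Transition matrix p*I + (1-p)*1 pi^T, whose stationary law is pi."""
    pi = np.asarray(stationary, float)
    K = pi.size
    return persistence * np.eye(K) + (1.0 - persistence) * np.tile(pi, (K, 1))


def simulate_chain(transition: np.ndarray, initial: np.ndarray, length: int,
                   seed: int) -> np.ndarray:
    """Sample a Markov chain of ``length`` states; deterministic per seed."""
    transition = np.asarray(transition, float)
    initial = np.asarray(initial, float)
    if length < 1:
        raise ValueError("length must be >= 1")
    if np.max(np.abs(transition.sum(axis=1) - 1.0)) > 1e-9:
        raise ValueError("transition rows must sum to 1")
    if abs(initial.sum() - 1.0) > 1e-9:
        raise ValueError("initial distribution must sum to 1")
    rng = np.random.default_rng(seed)
    u = rng.random(length)
    return sample_chain(
        np.ascontiguousarray(np.cumsum(transition, axis=1)),
        np.ascontiguousarray(np.cumsum(initial)),
        u,
    )


def _ramped_stationary(base: np.ndarray, length: int, rate: float,
                       boost_state: int, boost: float, tau_s: float) -> np.ndarray:
    t = np.arange(length) / rate
    w = boost * np.exp(-t / tau_s)
    course = (1.0 - w)[:, None] * base[None, :]
    course[:, boost_state] += w
    return course


def simulate_chain_mixture(stationary: np.ndarray, persistence: float,
                           length: int, seed: int,
                           ramp: tuple[int, float, float] | None = None,
                           rate: float = 1.0) -> np.ndarray:
    """Persistence-mixture chain, optionally with a decaying occupancy ramp.

    ``ramp = (state, boost, tau_s)`` transiently inflates one state's target
    occupancy at run onset, decaying with time constant ``tau_s`` seconds on
    the grid implied by ``rate``.
    """
    pi = np.asarray(stationary, float)
    if not 0.0 <= persistence < 1.0:
        raise ValueError("persistence must be in [0, 1)")
    if ramp is None:
        course = np.tile(pi, (length, 1))
    else:
        state, boost, tau = ramp
        course = _ramped_stationary(pi, length, rate, state, boost, tau)
    rng = np.random.default_rng(seed)
    return sample_chain_mixture(
        np.ascontiguousarray(course), persistence,
        rng.random(length), rng.random(length),
    )


def simulate_fmri_run(chain: np.ndarray, truth: GroundTruth, seed: int, *,
                      sampling_period: float = 2.0, condition: str = "EO",
                      subject: str = "s01", run_index: int = 0,
                      channels: Sequence[str] = FMRI_CHANNELS) -> RunSeries:
    """Gaussian-emission network series: one draw per chain step.

    At each time t the 13-channel observation is drawn from the Gaussian
    of the active state (mean ``state_means[chain[t]]``, covariance
    ``state_covs[chain[t]]``).
    """
    chain = np.asarray(chain, dtype=int)
    if chain.size and chain.max() >= truth.n_states:
        raise ValueError("chain contains a state index >= n_states")
    rng = np.random.default_rng(seed)
    C = truth.state_means.shape[1]
    chols = []
    for k in range(truth.n_states):
        try:
            chols.append(np.linalg.cholesky(truth.state_covs[k]))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"state {k} covariance is not SPD") from err
    white = rng.standard_normal((chain.size, C))
    data = truth.state_means[chain] + np.einsum(
        "tij,tj->ti", np.stack(chols)[chain], white)
    return RunSeries(
        data=data, sampling_period=sampling_period, condition=condition,
        subject=subject, run_index=run_index, modality="fmri",
        channels=tuple(channels),
    )


def _pink(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    T, C = shape
    white = rng.standard_normal((T, C))
    f = np.fft.rfftfreq(T)
    scale = np.where(f > 0, 1.0 / np.sqrt(f), 0.0)
    x = np.fft.irfft(np.fft.rfft(white, axis=0) * scale[:, None], n=T, axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_eeg_run(chain: np.ndarray, state_amplitudes: np.ndarray,
                     carrier_freq: float, raw_rate: float, noise_sd: float,
                     seed: int, *, condition: str = "EO", subject: str = "s01",
                     run_index: int = 0, channels: Sequence[str] = EEG_CHANNELS,
                     pink: bool = False) -> RunSeries:
    """Amplitude-modulated alpha oscillation on the raw EEG grid.

    Channel c at sample t is ``amp[chain[t], c] * sin(2 pi f t + phi_c)``
    plus broadband noise; per-channel phases are randomized per run.
    """
    amps = np.asarray(state_amplitudes, float)
    if np.any(amps < 0):
        raise ValueError("state amplitudes must be nonnegative")
    if not 0.0 < carrier_freq < raw_rate / 2.0:
        raise ValueError(
            f"carrier {carrier_freq} Hz must lie inside (0, Nyquist={raw_rate / 2}) Hz"
        )
    chain = np.asarray(chain, dtype=int)
    rng = np.random.default_rng(seed)
    C = amps.shape[1]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=C)
    t = np.arange(chain.size) / raw_rate
    carrier = np.sin(2.0 * np.pi * carrier_freq * t[:, None] + phases[None, :])
    noise = _pink(rng, (chain.size, C)) if pink else rng.standard_normal((chain.size, C))
    data = amps[chain] * carrier + noise_sd * noise
    return RunSeries(
        data=data, sampling_period=1.0 / raw_rate, condition=condition,
        subject=subject, run_index=run_index, modality="eeg",
        channels=tuple(channels),
    )


def simulate_voxel_bold(course: np.ndarray, beta_map: np.ndarray,
                        hrf_values: np.ndarray, noise_ar1: tuple[float, float],
                        seed: int) -> np.ndarray:
    """Parcel/voxel BOLD matrix driven by state courses through an HRF.

    ``course`` is either an integer chain (converted to one-hot) or a
    (T, K) probability course on the TR grid; each target row is
    sum_k beta_map[v, k] * (course_k convolved with the HRF) plus AR(1)
    noise with coefficient rho and innovation-matched SD:
    ``noise_ar1 = (rho, sd)``.
    """
    course = np.asarray(course)
    beta_map = np.asarray(beta_map, float)
    K = beta_map.shape[1]
    if course.ndim == 1:
        onehot = np.zeros((course.size, K))
        onehot[np.arange(course.size), course.astype(int)] = 1.0
        course = onehot
    T = course.shape[0]
    if hrf_values.size > T:
        raise ValueError("HRF kernel is longer than the run")
    rho, sd = noise_ar1
    if not abs(rho) < 1:
        raise ValueError("AR(1) coefficient must satisfy |rho| < 1")
    conv = np.empty_like(course)
    for k in range(K):
        conv[:, k] = np.convolve(course[:, k], hrf_values)[:T]
    signal = beta_map @ conv.T
    if sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.stack([
            ar1_noise(rng.standard_normal(T), rho) for _ in range(beta_map.shape[0])
        ])
        signal = signal + sd * noise
    return signal


# ---------------------------------------------------------------------------
# ground-truth parameter construction


def default_ground_truth(profile: EffectProfile, manifest: StudyManifest,
                         seed: int) -> GroundTruth:
    """Deterministic state parameters mirroring the study's phenomenology.

    Four canonical states: a sensory state (visual/auditory/somatomotor
    activation), a default-mode state, an attention/salience state, and a
    low-activity high-alpha state with elevated visual-channel covariance.
    """
    K = profile.n_states
    C = len(manifest.fmri_channels)
    if K != 4 or C != 13:
        # generic fallback: spread states on orthogonal-ish sign patterns
        rng = np.random.default_rng(subseed(seed, 999))
        P = rng.choice([-1.0, 0.0, 1.0], size=(K, C))
    else:
        P = np.zeros((K, C))
        P[0, [0, 1, 2, 3, 9, 10]] = 1.0      # sensory
        P[0, [5, 6]] = -0.5
        P[1, [5, 6, 7]] = 1.0                # default mode
        P[1, [0, 1, 2]] = -0.5
        P[2, [4, 8, 11, 12]] = 1.0           # attention / salience
        P[2, [5, 6]] = -0.5
        P[3, :] = -0.3                       # low-activity, high alpha
        P[3, [0, 1, 2]] = 0.2
    means = profile.fmri_mean_scale * P
    covs = np.tile(np.eye(C), (K, 1, 1))
    if K == 4 and C == 13:
        vis = np.ix_([0, 1, 2], [0, 1, 2])
        covs[3][vis] = 0.5
        np.fill_diagonal(covs[3], 1.0)
    gains = np.array([1.0, 0.9, 0.9, 0.95, 0.85, 0.85])[: len(manifest.eeg_channels)]
    levels = np.linspace(0.5, 1.2, K)
    levels[-1] = 2.5                          # high-alpha state stands out
    amps = np.outer(levels, gains)
    persistence = 1.0 - 1.0 / (profile.dwell_seconds * manifest.eeg_raw_rate)
    return GroundTruth(
        n_states=K,
        transition_by_condition={
            "EO": mixture_transition(profile.stationary_eo, persistence),
            "EC": mixture_transition(profile.stationary_ec, persistence),
        },
        initial_dist=np.asarray(profile.stationary_eo, float)
        / float(np.sum(profile.stationary_eo)),
        state_means=means,
        state_covs=covs,
        state_alpha_amplitudes=amps,
        chain_rate=manifest.eeg_raw_rate,
        seed=seed,
    )


def _default_beta_map(n_parcels: int, K: int, beta: float) -> np.ndarray:
    """Block-sparse parcel loading: each state drives its own parcel block."""
    bm = np.zeros((n_parcels, K))
    block = max(1, n_parcels // (K + 1))
    for k in range(K):
        bm[k * block:(k + 1) * block, k] = beta
    return bm


# ---------------------------------------------------------------------------
# full study assembly


@dataclass
class Study:
    """A complete synthetic study: both modalities plus ground truth."""

    manifest: StudyManifest
    profile: EffectProfile
    fmri: Dataset
    eeg: Dataset
    voxel_bold: dict[tuple[str, int], np.ndarray]
    beta_map: np.ndarray
    truth: GroundTruth
    seed: int

    def true_paths_tr(self) -> list[ViterbiPath]:
        """Ground-truth chains on the TR grid, packaged like decoded paths."""
        out = []
        for run in self.fmri:
            chain = self.truth.chain_at(run.key(), run.sampling_period)
            out.append(ViterbiPath(
                states=chain[: run.n_samples],
                sampling_period=run.sampling_period,
                n_states=self.truth.n_states,
                subject=run.subject, run_index=run.run_index,
                condition=run.condition,
            ))
        return out


def make_study(manifest: StudyManifest | None = None,
               profile: EffectProfile | None = None,
               seed: int = 0, include_eeg: bool = True,
               include_voxels: bool = True,
               hrf_values: np.ndarray | None = None) -> Study:
    """Generate a full EO/EC study: shared-chain EEG + fMRI runs + parcels.

    The latent chain for each run is sampled once at the EEG raw rate and
    decimated by index to the fMRI TR grid, so cross-modal occupancy
    agreement is exact at the ground-truth level. Identical
    (manifest, profile, seed) triples give identical studies.
    """
    manifest = manifest or StudyManifest()
    profile = profile or paperlike_profile()
    truth = default_ground_truth(profile, manifest, seed)
    K = truth.n_states
    rate = manifest.eeg_raw_rate
    tr = manifest.fmri_sampling_period
    n_raw = manifest.eeg_samples_per_run
    persistence = 1.0 - 1.0 / (profile.dwell_seconds * rate)
    if hrf_values is None and include_voxels:
        from .glm import double_gamma_hrf
        hrf_values = double_gamma_hrf(step=tr).values
    beta_map = _default_beta_map(profile.n_parcels, K, profile.parcel_beta)

    fmri_runs: list[RunSeries] = []
    eeg_runs: list[RunSeries] = []
    voxels: dict[tuple[str, int], np.ndarray] = {}
    for si, subject in enumerate(manifest.subjects):
        for ri, cond in enumerate(manifest.runs_per_subject):
            pi = profile.stationary_ec if cond == "EC" else profile.stationary_eo
            ramp = None
            if cond == "EC" and profile.ramp_boost is not None:
                ramp = (K - 1, profile.ramp_boost, profile.ramp_tau_s)
            chain = simulate_chain_mixture(
                pi, persistence, n_raw, subseed(seed, si, ri, 0),
                ramp=ramp, rate=rate,
            )
            truth.chain_paths[(subject, ri)] = chain
            step = tr * rate
            idx = np.floor(np.arange(manifest.fmri_samples_per_run) * step).astype(int)
            chain_tr = chain[idx]
            fmri_runs.append(simulate_fmri_run(
                chain_tr, truth, subseed(seed, si, ri, 1),
                sampling_period=tr, condition=cond, subject=subject,
                run_index=ri, channels=manifest.fmri_channels,
            ))
            if include_eeg:
                amps = truth.state_alpha_amplitudes
                if cond == "EC":
                    amps = amps * profile.ec_amp_scale
                eeg_runs.append(simulate_eeg_run(
                    chain, amps, profile.eeg_carrier_hz, rate,
                    profile.eeg_noise_sd, subseed(seed, si, ri, 2),
                    condition=cond, subject=subject, run_index=ri,
                    channels=manifest.eeg_channels, pink=profile.pink_noise,
                ))
            if include_voxels:
                voxels[(subject, ri)] = simulate_voxel_bold(
                    chain_tr, beta_map, hrf_values,
                    (profile.parcel_ar1, profile.parcel_noise_sd),
                    subseed(seed, si, ri, 3),
                )
    return Study(
        manifest=manifest, profile=profile,
        fmri=Dataset(fmri_runs),
        eeg=Dataset(eeg_runs) if include_eeg else Dataset([]),
        voxel_bold=voxels, beta_map=beta_map, truth=truth, seed=seed,
    )


def simulate_fo_study(n_subjects: int = 20, samples_per_run: int = 100,
                      stationary_eo: np.ndarray | None = None,
                      stationary_ec: np.ndarray | None = None,
                      persistence: float = 0.7,
                      runs: Sequence[str] = ("EO", "EC", "EO", "EC"),
                      sampling_period: float = 2.0,
                      seed: int = 0) -> list[ViterbiPath]:
    """Light-weight chain-only study for occupancy-contrast calibration.

    Samples the latent chains directly on the TR grid (no observations)
    and returns them packaged as labelled paths, ready for the state-metric
    and paired-contrast machinery. The default persistence 0.7 gives mean
    state visits of ~6-7 s at TR 2 s.
    """
    eo = np.asarray(stationary_eo if stationary_eo is not None
                    else [0.25, 0.25, 0.25, 0.25], float)
    ec = np.asarray(stationary_ec if stationary_ec is not None else eo, float)
    paths = []
    for si in range(n_subjects):
        for ri, cond in enumerate(runs):
            pi = ec if cond == "EC" else eo
            chain = simulate_chain_mixture(
                pi, persistence, samples_per_run, subseed(seed, si, ri, 7))
            paths.append(ViterbiPath(
                states=chain, sampling_period=sampling_period,
                n_states=eo.size, subject=f"s{si:02d}", run_index=ri,
                condition=cond,
            ))
    return paths


def shifted_occupancy(base: np.ndarray, state: int, shift: float) -> np.ndarray:
    """Raise one state's stationary occupancy by ``shift``, renormalizing
    the remaining mass proportionally."""
    pi = np.asarray(base, float).copy()
    target = pi[state] + shift
    if not 0.0 < target < 1.0:
        raise ValueError("shifted occupancy must stay inside (0, 1)")
    rest = 1.0 - target
    others = np.delete(pi, state)
    pi_new = np.empty_like(pi)
    pi_new[state] = target
    pi_new[np.arange(pi.size) != state] = others / others.sum() * rest
    return pi_new


# ---------------------------------------------------------------------------
# plain-text export


def save_study(study: Study, out_dir: str | Path) -> Path:
    """Write runs as TSV, manifest and ground truth as JSON; returns dir."""
    from .data import save_dataset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_dataset(study.fmri, out, manifest_name="fmri_manifest.json")
    if len(study.eeg):
        save_dataset(study.eeg, out, manifest_name="eeg_manifest.json")
    truth = study.truth
    gt = {
        "n_states": truth.n_states,
        "transition_by_condition": {
            c: a.tolist() for c, a in truth.transition_by_condition.items()
        },
        "initial_dist": truth.initial_dist.tolist(),
        "state_means": truth.state_means.tolist(),
        "state_covs": truth.state_covs.tolist(),
        "state_alpha_amplitudes": truth.state_alpha_amplitudes.tolist(),
        "chain_rate": truth.chain_rate,
        "seed": truth.seed,
        "chain_paths": {
            f"{s}:{r}": p.tolist() for (s, r), p in truth.chain_paths.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(gt))
    (out / "study_manifest.json").write_text(
        json.dumps(study.manifest.to_dict(), indent=2))
    return out
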