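import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from restdyn import mixture_transition, simulate_chain, subseed
from restdyn.data import Dataset, RunSeries

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def separated_means(n_states: int, n_channels: int, sep: float) -> np.ndarray:
    """Well-separated deterministic state means for recovery experiments."""
    m = np.zeros((n_states, n_channels))
    for k in range(n_states):
        m[k, k % n_channels] = sep * (1 if k % 2 == 0 else -1)
        m[k, (k + 1) % n_channels] = sep / 2
    return m


def make_separated_dataset(n_states=2, n_channels=2, sep=5.0, n_runs=10,
                           n_samples=300, persistence=0.8, seed=0,
                           noise_sd=1.0):
    """Gaussian-emission runs from a known chain; returns (dataset, chains, means)."""
    means = separated_means(n_states, n_channels, sep)
    trans = mixture_transition(np.full(n_states, 1.0 / n_states), persistence)
    init = np.full(n_states, 1.0 / n_states)
    runs, chains = [], []
    for r in range(n_runs):
        chain = simulate_chain(trans, init, n_samples, seed=subseed(seed, r, 0))
        chains.append(chain)
        noise = np.random.default_rng(subseed(seed, r, 1)).standard_normal(
            (n_samples, n_channels))
        runs.append(RunSeries(
            data=means[chain] + noise_sd * noise, sampling_period=2.0,
            condition="EO" if (r % 4) in (0, 2) else "EC",
            subject=f"s{r // 4:02d}", run_index=r % 4, modality="fmri",
        ))
    return Dataset(runs), chains, means


@pytest.fixture(scope="session")
def two_state_fit():
    """A converged 2-state VB fit on well-separated data, with its truth."""
    from restdyn import HMMSpec, fit_vb, standardize_inputs

    dataset, chains, means = make_separated_dataset(seed=11)
    std = standardize_inputs(dataset)
    model = fit_vb(std, HMMSpec(n_states=2, seed=1))
    return {"dataset": std, "raw": dataset, "chains": chains,
            "means": means, "model": model}


@pytest.fixture(scope="session")
def tiny_study():
    """Small shared-chain EO/EC study with both modalities and parcels."""
    from restdyn.synth import StudyManifest, make_study, paperlike_profile

    manifest = StudyManifest(
        subjects=("s01", "s02", "s03", "s04"),
        fmri_samples_per_run=100,
    )
    return make_study(manifest, paperlike_profile(), seed=5)
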