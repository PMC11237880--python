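"""Group-level hidden Markov model with multivariate Gaussian states.

The observation model is a multivariate Gaussian per state (mean vector +
covariance), inferred by variational Bayes: Dirichlet priors on the initial
distribution and on each transition-matrix row, and a Normal-Inverse-Wishart
prior on each state's (mean, covariance). Inference is performed at the
group level - one shared state set over all concatenated runs, with
per-run posterior state probability courses (gamma). The variational free
energy (negative evidence lower bound) is recorded every cycle and is
guaranteed non-increasing.

Runs are chained with the initial distribution re-applied at every run
boundary; no transition is counted across a boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import digamma, gammaln, multigammaln

from ._kernels import forward_backward_scaled, viterbi_path
from .data import Dataset, RunSeries

LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# specification / results containers


@dataclass
class HMMSpec:
    """Prior hyperparameters and stopping rule for a VB fit.

    ``scale`` is the Inverse-Wishart scale matrix of the emission prior
    (identity by default); ``dof`` its degrees of freedom (C + 2 by
    default, the smallest value giving a finite prior covariance mean).
    ``mean_precision`` scales how strongly state means shrink to
    ``prior_mean`` (weak by default: 0.1 pseudo-observations).
    """

    n_states: int
    dirichlet_alpha: float = 1.0
    prior_mean: np.ndarray | None = None
    mean_precision: float = 0.1
    scale: np.ndarray | None = None
    dof: float | None = None
    max_cycles: int = 500
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if self.dirichlet_alpha <= 0 or self.mean_precision <= 0:
            raise ValueError("prior concentrations must be positive")

    def to_dict(self) -> dict:
        d = {
            "n_states": self.n_states,
            "dirichlet_alpha": self.dirichlet_alpha,
            "mean_precision": self.mean_precision,
            "max_cycles": self.max_cycles,
            "tol": self.tol,
            "seed": self.seed,
            "dof": self.dof,
        }
        d["prior_mean"] = None if self.prior_mean is None else np.asarray(self.prior_mean).tolist()
        d["scale"] = None if self.scale is None else np.asarray(self.scale).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HMMSpec":
        d = dict(d)
        if d.get("prior_mean") is not None:
            d["prior_mean"] = np.asarray(d["prior_mean"], dtype=float)
        if d.get("scale") is not None:
            d["scale"] = np.asarray(d["scale"], dtype=float)
        return cls(**d)


@dataclass
class ViterbiPath:
    """Most-likely state sequence for one run, with its run labels."""

    states: np.ndarray              # (T,) int in [0, K)
    sampling_period: float
    n_states: int
    subject: str = ""
    run_index: int = 0
    condition: str = "EO"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def duration(self) -> float:
        return len(self) * self.sampling_period


@dataclass
class _Posterior:
    """Variational posterior hyperparameters (Normal-Wishart + Dirichlet)."""

    m: np.ndarray            # (K, C) posterior mean locations
    beta: np.ndarray         # (K,) mean-precision counts
    W: np.ndarray            # (K, C, C) Wishart scale matrices (precision)
    nu: np.ndarray           # (K,) Wishart degrees of freedom
    alpha_trans: np.ndarray  # (K, K) transition Dirichlet counts
    alpha_init: np.ndarray   # (K,) initial Dirichlet counts


@dataclass
class TrainedHMM:
    """Group-level fitted model: point estimates + full variational posterior."""

    state_means: np.ndarray          # (K, C) posterior expected means
    state_covs: np.ndarray           # (K, C, C) posterior expected covariances
    transition: np.ndarray           # (K, K) row-stochastic posterior mean
    initial: np.ndarray              # (K,) posterior mean
    gamma: list[np.ndarray]          # per run (T, K) state probability courses
    free_energy_trace: np.ndarray    # per-cycle free energy
    spec: HMMSpec
    run_keys: list[tuple[str, int]] = field(default_factory=list)
    _post: _Posterior | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.state_means.shape[0]

    @property
    def n_channels(self) -> int:
        return self.state_means.shape[1]

    @property
    def free_energy_final(self) -> float:
        return float(self.free_energy_trace[-1])


# ---------------------------------------------------------------------------
# standardization


def standardize_inputs(dataset: Dataset, per: str = "run") -> Dataset:
    """Amplitude-standardize every channel to mean 0, SD 1.

    ``per="run"`` (default) standardizes each run independently;
    ``per="subject"`` pools a subject's runs before computing the moments.
    Idempotent. Raises on a zero-variance channel, naming run and channel.
    """
    if per not in ("run", "subject"):
        raise ValueError("per must be 'run' or 'subject'")

    def _check(sd: np.ndarray, where: str, channels: Sequence[str]) -> None:
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance channel {channels[bad[0]]!r} in {where}; "
                "cannot standardize a constant signal"
            )

    out: list[RunSeries] = []
    if per == "run":
        for run in dataset:
            if run.n_samples < 2:
                raise ValueError(f"run {run.key()} has fewer than 2 samples")
            mu = run.data.mean(axis=0)
            sd = run.data.std(axis=0)
            _check(sd, f"run {run.key()}", run.channels)
            out.append(run.with_data((run.data - mu) / sd))
    else:
        by_subject: dict[str, list[RunSeries]] = {}
        for run in dataset:
            by_subject.setdefault(run.subject, []).append(run)
        for subject, runs in by_subject.items():
            pooled = np.concatenate([r.data for r in runs], axis=0)
            mu = pooled.mean(axis=0)
            sd = pooled.std(axis=0)
            _check(sd, f"subject {subject}", runs[0].channels)
            for r in runs:
                out.append(r.with_data((r.data - mu) / sd))
        # preserve original dataset order
        order = {r.key(): i for i, r in enumerate(dataset)}
        out.sort(key=lambda r: order[r.key()])
    return Dataset(out)


# ---------------------------------------------------------------------------
# exact inference given parameters


def forward_backward(log_obs_lik: np.ndarray, transition: np.ndarray,
                     initial: np.ndarray):
    """Posterior state marginals and pair marginals for one run.

    Parameters are ordinary (linear-scale) transition/initial
    probabilities; the observation term is given in log scale. Returns
    ``(gamma, xi, log_evidence)``.
    """
    log_b = np.asarray(log_obs_lik, dtype=float)
    if log_b.ndim != 2:
        raise ValueError("log_obs_lik must be (T, K)")
    if not np.all(np.isfinite(log_b)):
        raise ValueError("log_obs_lik contains non-finite values")
    transition = np.asarray(transition, dtype=float)
    initial = np.asarray(initial, dtype=float)
    rowmax = log_b.max(axis=1)
    b = np.exp(log_b - rowmax[:, None])
    gamma, xi, log_c = forward_backward_scaled(
        np.ascontiguousarray(b),
        np.ascontiguousarray(transition),
        np.ascontiguousarray(initial),
    )
    return gamma, xi, float(log_c + rowmax.sum())


def threshold_activation(gamma: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Binary activation matrix: state active where gamma exceeds threshold.

    With the default 0.8 threshold (>80% likelihood) at most one state can
    be active per time point.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    return np.asarray(gamma) > threshold


# ---------------------------------------------------------------------------
# variational E-step pieces


def _expected_log_lik(X: np.ndarray, post: _Posterior) -> np.ndarray:
    """E_q[log N(x | mu_k, Sigma_k)] for every sample and state."""
    T, C = X.shape
    K = post.m.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        W = post.W[k]
        nu = post.nu[k]
        sign, logdetW = np.linalg.slogdet(W)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "numerical covariance collapse in state posterior; "
                "consider a stronger emission prior (larger dof or scale)"
            )
        elogdet = (
            digamma(0.5 * (nu - np.arange(C))).sum() + C * np.log(2.0) + logdetW
        )
        L = np.linalg.cholesky(W)
        y = (X - post.m[k]) @ L
        quad = nu * np.einsum("ij,ij->i", y, y)
        out[:, k] = 0.5 * (elogdet - C * LOG2PI) - 0.5 * (C / post.beta[k] + quad)
    return out


def _dirichlet_elog(alpha: np.ndarray) -> np.ndarray:
    return digamma(alpha) - digamma(alpha.sum(axis=-1, keepdims=True))


def _kl_dirichlet(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    a, a0 = np.asarray(alpha, float), np.asarray(alpha0, float)
    s, s0 = a.sum(), a0.sum()
    return float(
        gammaln(s) - gammaln(a).sum() - gammaln(s0) + gammaln(a0).sum()
        + ((a - a0) * (digamma(a) - digamma(s))).sum()
    )


def _kl_normal_wishart(post: _Posterior, k: int, m0: np.ndarray, beta0: float,
                       W0_inv: np.ndarray, nu0: float) -> float:
    """KL(q(mu_k, Lambda_k) || prior) for one state."""
    C = m0.shape[0]
    m, beta, W, nu = post.m[k], post.beta[k], post.W[k], post.nu[k]
    _, logdetW = np.linalg.slogdet(W)
    sign0, logdetW0inv = np.linalg.slogdet(W0_inv)
    logdetW0 = -logdetW0inv
    elogdet = digamma(0.5 * (nu - np.arange(C))).sum() + C * np.log(2.0) + logdetW

    # expectation over Lambda of KL between the two conditional Normals
    dm = m - m0
    kl_norm = 0.5 * (
        C * (beta0 / beta - 1.0 + np.log(beta / beta0))
        + beta0 * nu * dm @ W @ dm
    )

    # KL between the Wishart factors
    def log_b(logdet_w: float, dof: float) -> float:
        return -0.5 * dof * logdet_w - 0.5 * dof * C * np.log(2.0) - multigammaln(0.5 * dof, C)

    kl_wish = (
        log_b(logdetW, nu) - log_b(logdetW0, nu0)
        + 0.5 * (nu - nu0) * elogdet
        + 0.5 * nu * (np.trace(W0_inv @ W) - C)
    )
    return float(kl_norm + kl_wish)


# ---------------------------------------------------------------------------
# VB fitting


def _init_posterior(X: np.ndarray, lengths: np.ndarray, spec: HMMSpec,
                    priors: dict) -> _Posterior:
    """Seeded k-means hard assignment followed by one M-step.

    A single random-restart k-means keeps the initialization genuinely
    stochastic across repeat seeds - repeat reliability is only a
    meaningful selection diagnostic when repeats can disagree.
    The k-means model is fit on the lexicographically sorted pooled matrix
    and then applied to the rows in their original order, so the
    initialization depends only on the multiset of samples - never on run
    concatenation order.
    """
    from sklearn.cluster import KMeans

    K = spec.n_states
    T = X.shape[0]
    if K > T:
        raise ValueError(f"n_states={K} exceeds total sample count {T}")
    order = np.lexsort(X.T[::-1])
    km = KMeans(n_clusters=K, n_init=1, init="random",
                random_state=spec.seed % (2 ** 31))
    km.fit(X[order])
    labels = km.predict(X)
    gamma = np.zeros((T, K))
    gamma[np.arange(T), labels] = 1.0
    xi_sum = np.zeros((K, K))
    init_counts = np.zeros(K)
    start = 0
    for ln in lengths:
        seg = labels[start:start + ln]
        init_counts[seg[0]] += 1.0
        np.add.at(xi_sum, (seg[:-1], seg[1:]), 1.0)
        start += ln
    return _m_step(X, gamma, xi_sum, init_counts, priors)


def _m_step(X: np.ndarray, gamma: np.ndarray, xi_sum: np.ndarray,
            init_counts: np.ndarray, priors: dict) -> _Posterior:
    C = X.shape[1]
    K = gamma.shape[1]
    m0, beta0, W0_inv, nu0, a0 = (
        priors["m0"], priors["beta0"], priors["W0_inv"], priors["nu0"], priors["a0"],
    )
    Nk = gamma.sum(axis=0)
    m = np.empty((K, C))
    beta = beta0 + Nk
    nu = nu0 + Nk
    W = np.empty((K, C, C))
    for k in range(K):
        if Nk[k] > 0:
            xbar = gamma[:, k] @ X / Nk[k]
            diff = X - xbar
            S = (gamma[:, k, None] * diff).T @ diff
        else:
            xbar = m0.copy()
            S = np.zeros((C, C))
        m[k] = (beta0 * m0 + Nk[k] * xbar) / beta[k]
        dm = xbar - m0
        W_inv = W0_inv + S + (beta0 * Nk[k] / beta[k]) * np.outer(dm, dm)
        W_inv = 0.5 * (W_inv + W_inv.T)
        try:
            W[k] = np.linalg.inv(W_inv)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "numerical covariance collapse during the M-step; "
                "consider a stronger emission prior (larger dof or scale)"
            ) from err
    return _Posterior(
        m=m, beta=beta, W=W, nu=nu,
        alpha_trans=a0 + xi_sum,
        alpha_init=a0 + init_counts,
    )


def _priors(spec: HMMSpec, C: int) -> dict:
    m0 = np.zeros(C) if spec.prior_mean is None else np.asarray(spec.prior_mean, float)
    scale = np.eye(C) if spec.scale is None else np.asarray(spec.scale, float)
    nu0 = float(C + 2) if spec.dof is None else float(spec.dof)
    if nu0 <= C - 1:
        raise ValueError(f"dof must exceed C - 1 = {C - 1}")
    return {
        "m0": m0,
        "beta0": float(spec.mean_precision),
        "W0_inv": scale,          # Inverse-Wishart scale = Wishart scale inverse
        "nu0": nu0,
        "a0": float(spec.dirichlet_alpha),
    }


def _e_step(X: np.ndarray, lengths: np.ndarray, post: _Posterior):
    """One full E-step over all runs. Returns stats and the ELBO data term."""
    K = post.m.shape[0]
    log_b_all = _expected_log_lik(X, post)
    elog_a = _dirichlet_elog(post.alpha_trans)
    elog_pi = _dirichlet_elog(post.alpha_init[None, :])[0]
    tilde_a = np.ascontiguousarray(np.exp(elog_a))
    tilde_pi = np.ascontiguousarray(np.exp(elog_pi))
    gammas: list[np.ndarray] = []
    xi_sum = np.zeros((K, K))
    init_counts = np.zeros(K)
    log_z = 0.0
    start = 0
    for ln in lengths:
        log_b = log_b_all[start:start + ln]
        rowmax = log_b.max(axis=1)
        b = np.ascontiguousarray(np.exp(log_b - rowmax[:, None]))
        gamma, xi, log_c = forward_backward_scaled(b, tilde_a, tilde_pi)
        log_z += log_c + rowmax.sum()
        gammas.append(gamma)
        if ln > 1:
            xi_sum += xi.sum(axis=0)
        init_counts += gamma[0]
        start += ln
    return gammas, xi_sum, init_counts, float(log_z)


def _kl_total(post: _Posterior, priors: dict) -> float:
    K = post.m.shape[0]
    a0 = priors["a0"]
    kl = _kl_dirichlet(post.alpha_init, np.full(K, a0))
    for j in range(K):
        kl += _kl_dirichlet(post.alpha_trans[j], np.full(K, a0))
    for k in range(K):
        kl += _kl_normal_wishart(post, k, priors["m0"], priors["beta0"],
                                 priors["W0_inv"], priors["nu0"])
    return kl


def fit_vb(dataset: Dataset, spec: HMMSpec) -> TrainedHMM:
    """Variational-Bayes fit of a group-level Gaussian HMM.

    A single shared state set is inferred over all runs concatenated; the
    state probability courses (gamma) stay resolved per run. Stops when the
    relative free-energy change drops below ``spec.tol`` or after
    ``spec.max_cycles`` cycles. Fully reproducible from ``spec.seed``.
    """
    X = dataset.concatenated()
    lengths = dataset.run_lengths()
    C = X.shape[1]
    priors = _priors(spec, C)
    post = _init_posterior(X, lengths, spec, priors)

    trace: list[float] = []
    gammas: list[np.ndarray] = []
    prev_f = np.inf
    for cycle in range(spec.max_cycles):
        gammas, xi_sum, init_counts, log_z = _e_step(X, lengths, post)
        f = -log_z + _kl_total(post, priors)
        trace.append(f)
        if np.isfinite(prev_f) and abs(prev_f - f) <= spec.tol * abs(prev_f):
            break
        if cycle == spec.max_cycles - 1:
            break
        post = _m_step(X, np.concatenate(gammas, axis=0), xi_sum, init_counts, priors)
        prev_f = f

    nu = post.nu
    covs = np.empty_like(post.W)
    for k in range(spec.n_states):
        covs[k] = np.linalg.inv(post.W[k]) / (nu[k] - C - 1)
    return TrainedHMM(
        state_means=post.m.copy(),
        state_covs=covs,
        transition=post.alpha_trans / post.alpha_trans.sum(axis=1, keepdims=True),
        initial=post.alpha_init / post.alpha_init.sum(),
        gamma=gammas,
        free_energy_trace=np.asarray(trace),
        spec=spec,
        run_keys=[r.key() for r in dataset],
        _post=post,
    )


def fit_vb_restarts(dataset: Dataset, spec: HMMSpec,
                    n_restarts: int = 3) -> TrainedHMM:
    """Fit with several derived-seed initializations; keep the lowest
    free energy. Restart seeds derive deterministically from ``spec.seed``."""
    from dataclasses import replace as _replace

    from .data import subseed

    fits = [
        fit_vb(dataset, _replace(spec, seed=subseed(spec.seed, r)))
        for r in range(n_restarts)
    ]
    return min(fits, key=lambda m: m.free_energy_final)


def free_energy(model: TrainedHMM, dataset: Dataset, return_parts: bool = False):
    """Variational free energy of a trained model evaluated on a dataset.

    On the training data this equals the final entry of the fit's
    free-energy trace. ``return_parts=True`` additionally returns the
    dataset-dependent term (-ELBO data part) and the dataset-independent
    KL penalty separately; the data term is additive over runs.
    """
    if model._post is None:
        raise ValueError("model lacks its variational posterior (loaded point model?)")
    if dataset.n_channels != model.n_channels:
        raise ValueError(
            f"channel mismatch: model has {model.n_channels}, data {dataset.n_channels}"
        )
    X = dataset.concatenated()
    lengths = dataset.run_lengths()
    _, _, _, log_z = _e_step(X, lengths, model._post)
    priors = _priors(model.spec, model.n_channels)
    kl = _kl_total(model._post, priors)
    f = -log_z + kl
    if return_parts:
        return f, -log_z, kl
    return f


def viterbi(model: TrainedHMM, run: RunSeries) -> ViterbiPath:
    """Most-likely state sequence for one run under the fitted model.

    Decoding scores use the variational expected log-parameters (the same
    quantities that drive the E-step), i.e. posterior point estimates
    rather than samples. Ties break toward the lower state index.
    """
    if run.n_samples == 0:
        raise ValueError("cannot decode an empty run")
    if run.n_channels != model.n_channels:
        raise ValueError(
            f"channel mismatch: model has {model.n_channels}, run {run.n_channels}"
        )
    if model._post is None:
        raise ValueError("model lacks its variational posterior")
    log_b = _expected_log_lik(run.data, model._post)
    elog_a = _dirichlet_elog(model._post.alpha_trans)
    elog_pi = _dirichlet_elog(model._post.alpha_init[None, :])[0]
    path, _ = viterbi_path(
        np.ascontiguousarray(log_b),
        np.ascontiguousarray(elog_a),
        np.ascontiguousarray(elog_pi),
    )
    return ViterbiPath(
        states=path,
        sampling_period=run.sampling_period,
        n_states=model.n_states,
        subject=run.subject,
        run_index=run.run_index,
        condition=run.condition,
    )


def decode_dataset(model: TrainedHMM, dataset: Dataset) -> list[ViterbiPath]:
    return [viterbi(model, run) for run in dataset]


def permute_states(model: TrainedHMM, perm: Sequence[int]) -> TrainedHMM:
    """Relabel states by ``perm`` (new index i takes old state perm[i]).

    All parameters, posteriors and gammas are permuted consistently, so
    every downstream metric is invariant up to the same relabelling.
    """
    p = np.asarray(perm, dtype=int)
    if sorted(p.tolist()) != list(range(model.n_states)):
        raise ValueError("perm must be a permutation of range(n_states)")
    post = model._post
    new_post = None
    if post is not None:
        new_post = _Posterior(
            m=post.m[p], beta=post.beta[p], W=post.W[p], nu=post.nu[p],
            alpha_trans=post.alpha_trans[np.ix_(p, p)],
            alpha_init=post.alpha_init[p],
        )
    return TrainedHMM(
        state_means=model.state_means[p],
        state_covs=model.state_covs[p],
        transition=model.transition[np.ix_(p, p)],
        initial=model.initial[p],
        gamma=[g[:, p] for g in model.gamma],
        free_energy_trace=model.free_energy_trace.copy(),
        spec=model.spec,
        run_keys=list(model.run_keys),
        _post=new_post,
    )


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrainedHMM, path: str | Path) -> None:
    """Serialize a trained model (including its variational posterior) to JSON."""
    post = model._post
    payload = {
        "state_means": model.state_means.tolist(),
        "state_covs": model.state_covs.tolist(),
        "transition": model.transition.tolist(),
        "initial": model.initial.tolist(),
        "free_energy_trace": model.free_energy_trace.tolist(),
        "spec": model.spec.to_dict(),
        "run_keys": [[s, int(i)] for s, i in model.run_keys],
        "posterior": None if post is None else {
            "m": post.m.tolist(), "beta": post.beta.tolist(),
            "W": post.W.tolist(), "nu": post.nu.tolist(),
            "alpha_trans": post.alpha_trans.tolist(),
            "alpha_init": post.alpha_init.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedHMM:
    d = json.loads(Path(path).read_text())
    post = None
    if d.get("posterior") is not None:
        p = d["posterior"]
        post = _Posterior(
            m=np.asarray(p["m"], float), beta=np.asarray(p["beta"], float),
            W=np.asarray(p["W"], float), nu=np.asarray(p["nu"], float),
            alpha_trans=np.asarray(p["alpha_trans"], float),
            alpha_init=np.asarray(p["alpha_init"], float),
        )
    return TrainedHMM(
        state_means=np.asarray(d["state_means"], float),
        state_covs=np.asarray(d["state_covs"], float),
        transition=np.asarray(d["transition"], float),
        initial=np.asarray(d["initial"], float),
        gamma=[],
        free_energy_trace=np.asarray(d["free_energy_trace"], float),
        spec=HMMSpec.from_dict(d["spec"]),
        run_keys=[(s, int(i)) for s, i in d.get("run_keys", [])],
        _post=post,
    )
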