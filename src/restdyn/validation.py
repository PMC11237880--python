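"""End-to-end validation experiments with quantitative summaries.

Each function runs one self-contained experiment from scratch - exact
inference against exhaustive enumeration, VB sanity, parameter recovery,
model-selection behaviour, metric identities, contrast calibration and
power, cross-modal recovery, GLM round trips, feature agreement and
pipeline determinism - and returns a flat dict of measured quantities.
All randomness derives from the supplied seed. Problem sizes are chosen
for complete desk-scale runs; docs/methods.md records them.
"""

from __future__ import annotations

import filecmp
import itertools
import tempfile
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import synth
from .data import Dataset, RunSeries, subseed
from .features import (
    POSTERIOR_CHANNELS, bandpass_alpha, envelope_dataset, epoch_and_downsample,
    hilbert_envelope, welch_alpha_power,
)
from .glm import (
    build_regressor, double_gamma_hrf, first_level_glm, group_level_test,
    subject_level_average,
)
from .hmm import (
    HMMSpec, decode_dataset, fit_vb, fit_vb_restarts, forward_backward,
    standardize_inputs,
)
from ._kernels import viterbi_path
from .metrics import (
    compare_conditions, fractional_occupancy, lifetimes, state_metrics_table,
    switching_rate,
)
from .selection import scan_states, select_model
from .windows import crossmodal_correlation, group_average_fo, windowed_fo


# ---------------------------------------------------------------------------
# shared synthetic builders


def separated_means(n_states: int, n_channels: int, sep: float) -> np.ndarray:
    m = np.zeros((n_states, n_channels))
    for k in range(n_states):
        m[k, k % n_channels] = sep * (1 if k % 2 == 0 else -1)
        m[k, (k + 1) % n_channels] = sep / 2
    return m


def gaussian_chain_dataset(n_states, n_channels, sep, n_runs, n_samples,
                           persistence, seed, noise_sd=1.0):
    means = separated_means(n_states, n_channels, sep)
    trans = synth.mixture_transition(np.full(n_states, 1 / n_states), persistence)
    init = np.full(n_states, 1 / n_states)
    runs, chains = [], []
    for r in range(n_runs):
        chain = synth.simulate_chain(trans, init, n_samples,
                                     seed=subseed(seed, r, 0))
        chains.append(chain)
        noise = np.random.default_rng(subseed(seed, r, 1)).standard_normal(
            (n_samples, n_channels))
        runs.append(RunSeries(
            data=means[chain] + noise_sd * noise, sampling_period=2.0,
            condition="EO" if (r % 4) in (0, 2) else "EC",
            subject=f"s{r // 4:02d}", run_index=r % 4, modality="fmri",
        ))
    return Dataset(runs), chains, means, trans


# ---------------------------------------------------------------------------
# 1. exact inference vs exhaustive enumeration


def _enumerate_reference(log_b, transition, initial):
    T, K = log_b.shape
    gamma = np.zeros((T, K))
    total = 0.0
    best_score, best_seq = -np.inf, None
    log_a = np.log(np.maximum(transition, 1e-300))
    log_pi = np.log(np.maximum(initial, 1e-300))
    for seq in itertools.product(range(K), repeat=T):
        lp = log_pi[seq[0]] + log_b[0, seq[0]]
        for t in range(1, T):
            lp += log_a[seq[t - 1], seq[t]] + log_b[t, seq[t]]
        p = np.exp(lp)
        total += p
        for t in range(T):
            gamma[t, seq[t]] += p
        if lp > best_score:
            best_score, best_seq = lp, seq
    return gamma / total, np.log(total), np.array(best_seq), best_score


def check_exact_inference(seed: int, n_instances: int = 100) -> dict:
    """Forward-backward and Viterbi vs brute-force enumeration, K<=3, T<=8."""
    rng = np.random.default_rng(subseed(seed, 1))
    g_err = z_err = v_gap = 0.0
    for _ in range(n_instances):
        K = int(rng.integers(1, 4))
        T = int(rng.integers(1, 9))
        log_b = rng.normal(scale=2.0, size=(T, K))
        A = rng.dirichlet(np.ones(K), size=K)
        pi = rng.dirichlet(np.ones(K))
        gamma, _, log_z = forward_backward(log_b, A, pi)
        g_ref, log_z_ref, v_ref, s_ref = _enumerate_reference(log_b, A, pi)
        _, score = viterbi_path(log_b, np.log(A), np.log(pi))
        g_err = max(g_err, float(np.abs(gamma - g_ref).max()))
        z_err = max(z_err, abs(log_z - log_z_ref))
        v_gap = max(v_gap, abs(score - s_ref))
    return {
        "fb_oracle_max_gamma_error": g_err,
        "fb_oracle_max_logz_error": z_err,
        "viterbi_oracle_max_score_gap": v_gap,
        "n": n_instances,
    }


# ---------------------------------------------------------------------------
# 2. VB sanity


def check_vb_sanity(seed: int) -> dict:
    """Free-energy monotonicity across fits; K=1 moment recovery."""
    worst_increase = -np.inf
    for k, sep in ((2, 5.0), (3, 3.0)):
        ds, _, _, _ = gaussian_chain_dataset(k, 2, sep, 8, 200, 0.8,
                                             subseed(seed, 2, k))
        model = fit_vb(standardize_inputs(ds), HMMSpec(n_states=k, seed=seed))
        tr = model.free_energy_trace
        rel = np.diff(tr) / np.abs(tr[:-1])
        worst_increase = max(worst_increase, float(rel.max()))
    ds, _, _, _ = gaussian_chain_dataset(1, 2, 0.0, 6, 300, 0.8, subseed(seed, 2, 1))
    m1 = fit_vb(standardize_inputs(ds), HMMSpec(n_states=1, seed=seed))
    return {
        "fe_max_relative_increase": worst_increase,
        "k1_mean_abs_error": float(np.abs(m1.state_means).max()),
        "k1_cov_identity_error": float(np.abs(m1.state_covs[0] - np.eye(2)).max()),
    }


# ---------------------------------------------------------------------------
# 3. parameter recovery


def check_parameter_recovery(seed: int) -> dict:
    """20 runs x 500 samples, K = 2..4, mean separation 4, unit noise."""
    mean_err = fo_err = l1_err = 0.0
    acc_min = 1.0
    for K in (2, 3, 4):
        C = max(3, K)
        ds, chains, means, trans = gaussian_chain_dataset(
            K, C, 4.0, 20, 500, 0.8, subseed(seed, 3, K))
        model = fit_vb_restarts(ds, HMMSpec(n_states=K, seed=subseed(seed, 3, K, 1)))
        D = np.linalg.norm(model.state_means[:, None] - means[None], axis=2)
        ri, ci = linear_sum_assignment(D)
        perm = np.empty(K, int)
        perm[ci] = ri
        mean_err = max(mean_err, float(np.abs(model.state_means[perm] - means).max()))
        paths = decode_dataset(model, ds)
        acc = np.mean(np.concatenate([perm[c] == p.states
                                      for p, c in zip(paths, chains)]))
        acc_min = min(acc_min, float(acc))
        fo_err = max(fo_err, max(
            float(np.abs(fractional_occupancy(p)[perm]
                         - fractional_occupancy(c, K)).max())
            for p, c in zip(paths, chains)))
        l1_err = max(l1_err, float(
            np.abs(model.transition[np.ix_(perm, perm)] - trans).sum(axis=1).max()))
    return {
        "recovery_state_mean_error": mean_err,
        "recovery_viterbi_accuracy": acc_min,
        "recovery_fo_error": fo_err,
        "recovery_transition_l1_error": l1_err,
    }


# ---------------------------------------------------------------------------
# 4. model selection behaviour


def check_model_selection(seed: int) -> dict:
    """Scan K in {2, 3, 6} with 5 repeats on true-K=3 data (separation 4)."""
    ds, _, _, _ = gaussian_chain_dataset(3, 3, 4.0, 12, 300, 0.8, subseed(seed, 4))
    std = standardize_inputs(ds)
    report = scan_states(std, [2, 3, 6], repeats=5, base_seed=subseed(seed, 4, 1))
    fe = report.entries.groupby("k")["free_energy"].mean()
    k, _ = select_model(report, reliability_floor=0.8)
    return {
        "selection_reliability_k3": float(report.mean_reliability[3]),
        "selection_reliability_k6": float(report.mean_reliability[6]),
        "selection_fe_k2": float(fe[2]),
        "selection_fe_k3": float(fe[3]),
        "selection_chosen_k": float(k),
    }


# ---------------------------------------------------------------------------
# 5. metric identities


def check_metric_identities(seed: int) -> dict:
    rng = np.random.default_rng(subseed(seed, 5))
    from .hmm import ViterbiPath

    p = ViterbiPath(states=rng.integers(0, 3, 600), sampling_period=2.0,
                    n_states=3)
    fo = fractional_occupancy(p)
    lt = lifetimes(p)
    lt_err = max(abs(lt[k].sum() - fo[k] * p.duration) for k in range(3))
    sw = switching_rate(np.asarray(rng.integers(0, 4, 10_000)))
    course = windowed_fo(p, window_length=10.0)   # 5 samples per window, exact tiling
    part_err = float(np.abs(course.values.mean(axis=0) - fo).max())
    return {
        "fo_sum_error": float(abs(fo.sum() - 1.0)),
        "lifetime_occupancy_identity_error": float(lt_err),
        "switching_rate_uniform_k4": float(sw),
        "windowed_fo_partition_error": part_err,
    }


# ---------------------------------------------------------------------------
# 6. condition-contrast calibration and power


def check_contrast_calibration(seed: int, n_reps: int = 200,
                               n_subjects: int = 20,
                               samples_per_run: int = 100) -> dict:
    """Null familywise error and detection of a 0.1 occupancy shift."""
    base = np.full(4, 0.25)
    shifted = synth.shifted_occupancy(base, 0, 0.1)
    fwe = 0
    for rep in range(n_reps):
        paths = synth.simulate_fo_study(
            n_subjects=n_subjects, samples_per_run=samples_per_run,
            stationary_eo=base, stationary_ec=base, persistence=0.7,
            seed=subseed(seed, 6, rep))
        res = compare_conditions(state_metrics_table(paths))
        if (res["p_adjusted"] < 0.05).any():
            fwe += 1
    detect = 0
    for rep in range(n_reps):
        paths = synth.simulate_fo_study(
            n_subjects=n_subjects, samples_per_run=samples_per_run,
            stationary_eo=base, stationary_ec=shifted, persistence=0.7,
            seed=subseed(seed, 7, rep))
        res = compare_conditions(state_metrics_table(paths))
        row = res[res["state"] == 0].iloc[0]
        if row["p_adjusted"] < 0.05 and row["difference"] < 0:  # EC > EO
            detect += 1
    return {
        "contrast_familywise_error_rate": fwe / n_reps,
        "contrast_detection_rate": detect / n_reps,
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# 7. cross-modal recovery and null


def check_crossmodal(seed: int, n_subjects: int = 8,
                     samples_per_run: int = 300) -> dict:
    """Shared-chain study: EC-run matched-state cross-modal correlation
    for states recovered by both models; plus an independent-chain null.

    The matched correlation is measured on EC runs, where the injected
    post-eye-closure dynamics provide genuine shared occupancy structure;
    EO-run courses are near-constant so their correlation carries no
    recovery information.
    """
    manifest = synth.StudyManifest(
        subjects=tuple(f"s{i:02d}" for i in range(n_subjects)),
        fmri_samples_per_run=samples_per_run,
    )
    study = synth.make_study(manifest, synth.paperlike_profile(),
                             seed=subseed(seed, 8), include_voxels=False)
    K = study.truth.n_states
    fmri = standardize_inputs(study.fmri)
    fmri_model = fit_vb_restarts(fmri, HMMSpec(n_states=K, seed=subseed(seed, 8, 1)))
    env = standardize_inputs(envelope_dataset(study.eeg))
    eeg_model = fit_vb_restarts(env, HMMSpec(n_states=K, seed=subseed(seed, 8, 2)))

    def truth_match(model, ds):
        tc = np.concatenate([
            study.truth.chain_at(r.key(), r.sampling_period)[: r.n_samples]
            for r in ds
        ])
        gc = np.concatenate(model.gamma)
        corr = np.zeros((K, K))
        for i in range(K):
            oh = (tc == i).astype(float)
            for j in range(K):
                corr[i, j] = np.corrcoef(oh, gc[:, j])[0, 1]
        ri, ci = linear_sum_assignment(-corr)
        return dict(zip(ri.tolist(), ci.tolist())), corr[ri, ci]

    fmap, fcorr = truth_match(fmri_model, fmri)
    emap, ecorr = truth_match(eeg_model, env)
    recovered = [k for k in range(K) if fcorr[k] > 0.7 and ecorr[k] > 0.7]
    fmri_paths = decode_dataset(fmri_model, fmri)
    eeg_paths = decode_dataset(eeg_model, env)
    ec_runs = sorted({p.run_index for p in fmri_paths if p.condition == "EC"})
    rs = []
    for ri_ in ec_runs:
        fg = group_average_fo([windowed_fo(p) for p in fmri_paths
                               if p.run_index == ri_])
        eg = group_average_fo([windowed_fo(p) for p in eeg_paths
                               if p.run_index == ri_])
        cm = crossmodal_correlation(fg, eg)
        rs.extend(cm.r[fmap[k], emap[k]] for k in recovered)
    matched_r = float(np.mean(rs)) if rs else float("nan")

    # independent-chain null at m = 30 (6 x 5 states)
    from .hmm import ViterbiPath

    n_cells = sig_cells = 0
    for rep in range(100):
        rng_seed = subseed(seed, 9, rep)
        groups = []
        for Km, stream in ((6, 0), (5, 1)):
            courses = []
            for s in range(10):
                chain = synth.simulate_chain_mixture(
                    np.full(Km, 1 / Km), 0.7, 300,
                    subseed(rng_seed, Km, s, stream))
                courses.append(windowed_fo(ViterbiPath(
                    states=chain, sampling_period=2.0, n_states=Km)))
            groups.append(group_average_fo(courses))
        cm = crossmodal_correlation(groups[0], groups[1])
        sig_cells += int(np.nansum(cm.p_adjusted < 0.05))
        n_cells += cm.m_comparisons
    return {
        "crossmodal_matched_r_ec": matched_r,
        "crossmodal_states_recovered_both": float(len(recovered)),
        "crossmodal_null_significant_fraction": sig_cells / n_cells,
    }


# ---------------------------------------------------------------------------
# 8. GLM round trip and planted recovery


def check_glm(seed: int) -> dict:
    rng = np.random.default_rng(subseed(seed, 10))
    # noiseless round trip
    T, V, K = 200, 12, 3
    hrf = double_gamma_hrf(step=2.0)
    chain = rng.integers(0, K, size=T)
    beta_map = rng.normal(size=(V, K))
    Y = synth.simulate_voxel_bold(chain, beta_map, hrf.values, (0.0, 0.0), seed=0)
    onehot = np.eye(K)[chain]
    X = np.column_stack([
        build_regressor(onehot[:, k], rate=0.5, tr=2.0, hrf=hrf, n_out=T)
        for k in range(K)
    ])
    rt_err = float(np.abs(first_level_glm(Y, X).betas - beta_map).max())

    # planted-effect group recovery: 10 of 200 parcels at beta = 0.5 sigma
    n_sub, n_runs, T2, V2 = 20, 2, 200, 200
    planted = np.arange(10)
    beta = np.zeros(V2)
    beta[planted] = 0.5
    subj_maps = []
    for s in range(n_sub):
        run_res = []
        for r in range(n_runs):
            rr = np.random.default_rng(subseed(seed, 11, s, r))
            course = synth.simulate_chain_mixture(
                np.array([0.5, 0.5]), 0.7, T2, subseed(seed, 12, s, r))
            x = build_regressor((course == 0).astype(float), rate=0.5, tr=2.0,
                                hrf=hrf, n_out=T2)
            Yr = beta[:, None] * x[None, :] + rr.standard_normal((V2, T2))
            run_res.append(first_level_glm(Yr, x))
        subj_maps.append(subject_level_average(run_res, ["EO"] * n_runs)["EO"][:, 0])
    g = group_level_test(np.stack(subj_maps))
    recovered = int(g.significant[planted].sum())
    false_pos = int(g.significant.sum() - recovered)

    h = double_gamma_hrf(step=0.01)
    return {
        "glm_beta_roundtrip_error": rt_err,
        "glm_planted_parcels_recovered": float(recovered),
        "glm_false_positive_parcels": float(false_pos),
        "hrf_value_at_zero": float(h.values[0]),
        "hrf_peak_time_s": float(h.times[np.argmax(h.values)]),
    }


# ---------------------------------------------------------------------------
# 9. feature agreement


def check_features(seed: int) -> dict:
    rate = 200.0
    t = np.arange(int(60 * rate)) / rate
    x = np.sin(2 * np.pi * 10.0 * t)
    run = RunSeries(data=np.tile(x[:, None], (1, 6)), sampling_period=1 / rate,
                    condition="EO", subject="s01", run_index=0, modality="eeg",
                    channels=POSTERIOR_CHANNELS)
    filtered = bandpass_alpha(run)
    epochs, ds = epoch_and_downsample(filtered, tr=2.0, target_rate=40.0)
    welch = welch_alpha_power(epochs, 40.0, POSTERIOR_CHANNELS)
    env = hilbert_envelope(ds).data[:, 0] ** 2 / 2
    n = epochs.shape[0]
    env_epoch = env[: n * 80].reshape(n, 80).mean(axis=1)
    ratio = float((env_epoch[2:-2] / welch[2:-2]).mean())
    return {
        "welch_tone_band_power": float(welch.mean()),
        "envelope_vs_welch_power_ratio": ratio,
        "epoch_samples": float(epochs.shape[1]),
    }


# ---------------------------------------------------------------------------
# 10. end-to-end determinism


def check_determinism(seed: int) -> dict:
    """Run the reduced end-to-end driver twice; compare bytes."""
    from .pipeline import PipelineConfig, run_paperlike_experiment

    cfg = PipelineConfig(n_subjects=4, fmri_samples_per_run=100,
                         k_list=(2, 3), repeats=2)
    with tempfile.TemporaryDirectory() as tmp:
        a, b = Path(tmp) / "a", Path(tmp) / "b"
        run_paperlike_experiment(cfg, seed, a)
        run_paperlike_experiment(cfg, seed, b)
        names = sorted(p.name for p in a.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
    return {
        "determinism_files_compared": float(len(names)),
        "determinism_files_identical": float(len(match)),
        "determinism_identical": float(not mismatch and not errors),
    }


ALL_CHECKS = [
    check_exact_inference,
    check_vb_sanity,
    check_parameter_recovery,
    check_model_selection,
    check_metric_identities,
    check_contrast_calibration,
    check_crossmodal,
    check_glm,
    check_features,
    check_determinism,
]
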