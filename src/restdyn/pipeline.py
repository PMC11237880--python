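"""End-to-end study driver and report writing.

``run_paperlike_experiment`` chains every stage on a synthetic EO/EC
study: simulate -> alpha features -> train/select both HMMs -> state
metrics + condition contrasts (full runs and first quarter) -> sliding
windows + cross-modal correlation -> state spectra -> HRF GLM mapping.
All outputs are plain TSV/JSON in one report directory; every table
carries a header comment with the config hash and seed, and the whole
bundle is byte-identical under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .data import Dataset, subseed
from .features import (
    alpha_condition_test, alpha_power_course, envelope_dataset,
)
from .glm import (
    build_regressor, double_gamma_hrf, first_level_glm, group_level_test,
    subject_level_average,
)
from .hmm import decode_dataset, standardize_inputs
from .metrics import (
    compare_conditions, restrict_first_quarter, state_metrics_table,
)
from .selection import scan_states, select_model
from .spectra import spectra_table, weighted_multitaper
from .windows import crossmodal_correlation, group_average_fo, windowed_fo


@dataclass
class PipelineConfig:
    """Defaults mirror the emulated study design wherever it states one:
    7-13 Hz band, TR 2 s, 10 s windows, state counts 2-15 with 5 repeats,
    reliability floor 0.8, activation threshold 0.8."""

    n_subjects: int = 21
    fmri_samples_per_run: int = 300
    eeg_raw_rate: float = 200.0
    eeg_target_rate: float = 40.0
    band: tuple[float, float] = (7.0, 13.0)
    tr: float = 2.0
    window_length: float = 10.0
    k_list: tuple[int, ...] = tuple(range(2, 16))
    repeats: int = 5
    reliability_floor: float = 0.8
    activation_threshold: float = 0.8
    alpha: float = 0.05
    first_quarter: bool = True
    gamma_fo: bool = False
    prewhiten: bool = False
    effect_profile: str = "paperlike"

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.window_length <= 0:
            raise ValueError("TR and window length must be positive")
        if not 0 < self.activation_threshold < 1:
            raise ValueError("activation threshold must be in (0, 1)")

    @classmethod
    def desk_scale(cls, **overrides) -> "PipelineConfig":
        """A reduced configuration sized for quick complete runs: fewer
        subjects, shorter runs and a narrow state scan."""
        kw = dict(
            n_subjects=6, fmri_samples_per_run=150,
            k_list=(2, 3, 4), repeats=2,
        )
        kw.update(overrides)
        return cls(**kw)

    def manifest(self) -> synth.StudyManifest:
        return synth.StudyManifest(
            subjects=tuple(f"s{i:02d}" for i in range(1, self.n_subjects + 1)),
            fmri_samples_per_run=self.fmri_samples_per_run,
            fmri_sampling_period=self.tr,
            eeg_raw_rate=self.eeg_raw_rate,
        )

    def profile(self) -> synth.EffectProfile:
        if self.effect_profile == "paperlike":
            return synth.paperlike_profile()
        if self.effect_profile == "null":
            return synth.null_profile()
        raise ValueError(f"unknown effect profile {self.effect_profile!r}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs stay on disk."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _contrast_tables(paths, header: str, out: Path, prefix: str) -> dict:
    table = state_metrics_table(paths)
    _write_tsv(table, out / f"{prefix}_state_metrics.tsv", header)
    result = {"table": table}
    for metric, name in (("fractional_occupancy", "fo_contrasts"),
                         ("switching_rate", "switching_contrast")):
        try:
            contrast = compare_conditions(table, metric)
        except ValueError as err:
            # e.g. zero-variance differences on very short runs; recorded,
            # not fatal, and deterministic either way
            (out / f"{prefix}_{name}.tsv").write_text(
                f"# {header}\n# contrast unavailable: {err}\n")
            contrast = None
        else:
            _write_tsv(contrast, out / f"{prefix}_{name}.tsv", header)
        result["fo" if metric == "fractional_occupancy" else "switching"] = contrast
    return result


def run_paperlike_experiment(config: PipelineConfig, seed: int,
                             out_dir: str | Path) -> dict:
    """Run the full synthetic experiment; returns the in-memory report.

    Any stage failure raises ``StageError`` naming the stage; outputs of
    completed stages remain in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"config={config.digest()} seed={seed}"
    (out / "config.json").write_text(json.dumps(
        {"config": asdict(config), "seed": seed, "digest": config.digest()},
        indent=2, default=list))
    report: dict = {"seed": seed}

    stage = "simulate"
    try:
        study = synth.make_study(config.manifest(), config.profile(), seed=seed)

        stage = "features"
        courses = [alpha_power_course(run, tr=config.tr,
                                      target_rate=config.eeg_target_rate,
                                      band=config.band)
                   for run in study.eeg]
        alpha_test = alpha_condition_test(courses)
        (out / "alpha_condition_test.json").write_text(
            json.dumps(alpha_test.as_dict(), indent=2))
        report["alpha_test"] = alpha_test
        env = envelope_dataset(study.eeg, band=config.band,
                               target_rate=config.eeg_target_rate, tr=config.tr)

        stage = "train-fmri"
        fmri_std = standardize_inputs(study.fmri)
        fmri_report = scan_states(fmri_std, config.k_list, config.repeats,
                                  base_seed=subseed(seed, 101))
        select_model(fmri_report, config.reliability_floor, fallback=True)
        fmri_model = fmri_report.chosen_model
        fmri_paths = decode_dataset(fmri_model, fmri_std)
        _write_tsv(fmri_report.entries, out / "fmri_selection.tsv", header)

        stage = "train-eeg"
        env_std = standardize_inputs(env)
        eeg_report = scan_states(env_std, config.k_list, config.repeats,
                                 base_seed=subseed(seed, 102))
        select_model(eeg_report, config.reliability_floor, fallback=True)
        eeg_model = eeg_report.chosen_model
        eeg_paths = decode_dataset(eeg_model, env_std)
        _write_tsv(eeg_report.entries, out / "eeg_selection.tsv", header)
        (out / "selection_summary.json").write_text(json.dumps({
            "fmri": {"chosen": list(fmri_report.chosen),
                     "rationale": fmri_report.rationale,
                     "mean_reliability": fmri_report.mean_reliability},
            "eeg": {"chosen": list(eeg_report.chosen),
                    "rationale": eeg_report.rationale,
                    "mean_reliability": eeg_report.mean_reliability},
        }, indent=2))
        report["fmri_selection"] = fmri_report
        report["eeg_selection"] = eeg_report

        stage = "metrics"
        report["fmri_metrics"] = _contrast_tables(fmri_paths, header, out, "fmri")
        report["eeg_metrics"] = _contrast_tables(eeg_paths, header, out, "eeg")
        if config.first_quarter:
            report["fmri_metrics_q1"] = _contrast_tables(
                restrict_first_quarter(fmri_paths), header, out, "fmri_q1")
            report["eeg_metrics_q1"] = _contrast_tables(
                restrict_first_quarter(eeg_paths), header, out, "eeg_q1")

        stage = "windows"
        n_runs = len(config.manifest().runs_per_subject)
        rows = []
        crossmodal = {}
        for ri in range(n_runs):
            f_courses = [windowed_fo(p, config.window_length)
                         for p in fmri_paths if p.run_index == ri]
            e_courses = [windowed_fo(p, config.window_length)
                         for p in eeg_paths if p.run_index == ri]
            f_group = group_average_fo(f_courses)
            e_group = group_average_fo(e_courses)
            cm = crossmodal_correlation(f_group, e_group)
            crossmodal[ri] = cm
            for i in range(cm.r.shape[0]):
                for j in range(cm.r.shape[1]):
                    rows.append({
                        "run_index": ri, "condition": f_group.condition,
                        "fmri_state": i, "eeg_state": j,
                        "r": cm.r[i, j], "p": cm.p[i, j],
                        "p_adjusted": cm.p_adjusted[i, j],
                        "n_windows": cm.n_windows,
                    })
            for name, g in (("fmri", f_group), ("eeg", e_group)):
                df = pd.DataFrame(g.values,
                                  columns=[f"state{k}" for k in range(g.n_states)])
                df.insert(0, "window", np.arange(g.n_windows))
                _write_tsv(df, out / f"group_windowfo_{name}_run{ri}.tsv", header)
        _write_tsv(pd.DataFrame(rows), out / "crossmodal_correlations.tsv", header)
        report["crossmodal"] = crossmodal

        stage = "spectra"
        env_concat = env_std.concatenated()
        gamma_concat = np.concatenate(eeg_model.gamma, axis=0)
        spec = weighted_multitaper(env_concat, config.eeg_target_rate,
                                   gamma_concat, window_length=config.tr)
        _write_tsv(spectra_table(spec, env_std[0].channels),
                   out / "eeg_state_spectra.tsv", header)
        report["spectra"] = spec

        stage = "glm"
        K_e = eeg_model.n_states
        hrf = double_gamma_hrf(step=1.0 / config.eeg_target_rate)
        by_subject: dict[str, tuple[list, list]] = {}
        for run, gamma in zip(env_std, eeg_model.gamma):
            X = np.column_stack([
                build_regressor(gamma[:, k], config.eeg_target_rate,
                                tr=config.tr, hrf=hrf,
                                n_out=config.fmri_samples_per_run)
                for k in range(K_e)
            ])
            Y = study.voxel_bold[run.key()]
            res = first_level_glm(Y, X, prewhiten_ar1=config.prewhiten)
            runs, conds = by_subject.setdefault(run.subject, ([], []))
            runs.append(res)
            conds.append(run.condition)
        subj_maps = {"EO": [], "EC": []}
        for subject, (results, conds) in by_subject.items():
            maps = subject_level_average(results, conds)
            for cond in ("EO", "EC"):
                subj_maps[cond].append(maps[cond])
        glm_rows = []
        group_results = {}
        for k in range(K_e):
            maps_k = {c: np.stack([m[:, k] for m in subj_maps[c]])
                      for c in ("EO", "EC")}
            for contrast in ("EO", "EC", "EO-EC"):
                g = group_level_test(maps_k, contrast, alpha=config.alpha)
                group_results[(k, contrast)] = g
                for v in range(g.t.size):
                    glm_rows.append({
                        "eeg_state": k, "contrast": contrast, "parcel": v,
                        "t": g.t[v], "p": g.p[v], "p_adjusted": g.p_adjusted[v],
                        "significant": bool(g.significant[v]),
                    })
        _write_tsv(pd.DataFrame(glm_rows), out / "glm_group_maps.tsv", header)
        report["glm"] = group_results
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err

    stage_summary = {
        "alpha_eo_minus_ec": alpha_test.mean_diff,
        "alpha_p": alpha_test.p,
        "fmri_chosen": list(fmri_report.chosen),
        "eeg_chosen": list(eeg_report.chosen),
        "n_crossmodal_runs": len(crossmodal),
        "stages_completed": [
            "simulate", "features", "train-fmri", "train-eeg", "metrics",
            "windows", "spectra", "glm",
        ],
    }
    (out / "summary.json").write_text(json.dumps(stage_summary, indent=2))
    report["summary"] = stage_summary
    return report
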