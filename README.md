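# restdyn

Brain-state dynamics of eyes-open (EO) vs eyes-closed (EC) rest:
group-level hidden Markov modelling of multichannel neuroimaging time
series, with model selection, Viterbi state metrics and condition
contrasts, sliding-window occupancy dynamics, EEG–fMRI cross-modal
correlation, alpha-band feature extraction, state spectra and
haemodynamic GLM mapping — exercised end to end on a synthetic EO/EC
study generator with known ground truth.

It is written for researchers analysing resting-state recordings
(network/parcel BOLD series, band-limited EEG envelopes) who want a
tested, reproducible implementation of the brain-state workflow rather
than a one-off script stack.

## The model in brief

Standardized observations $x_t \in \mathbb{R}^C$ are emitted by a hidden
chain $z_t \in \{1,\dots,K\}$:

$$x_t \mid z_t = k \sim \mathcal{N}(\mu_k, \Sigma_k), \qquad
  p(z_t = k \mid z_{t-1} = j) = A_{jk},$$

so each *brain state* is a mean-activity pattern plus a covariance
(functional connectivity) structure. Parameters are inferred by
variational Bayes (Dirichlet priors on $\pi$ and the rows of $A$,
Normal–Inverse-Wishart on each $(\mu_k, \Sigma_k)$) at the group level:
one state set across all runs, per-run posterior state probabilities
$\gamma_{tk}$, and a variational free energy that decreases every cycle.
The number of states is chosen by scanning $K$ with repeated fits and
balancing free energy, per-run maximum fractional occupancy, and repeat
reliability (mean correlation of assignment-matched $\gamma$ courses
across repeats). Decoded Viterbi paths yield fractional occupancy,
lifetimes, interval times and switching rates, which are compared between
EO and EC with paired t-tests and Bonferroni correction. See
`docs/methods.md` for the full account.

## Worked example

Simulate a small EO/EC study, fit a 4-state group HMM to the fMRI-like
network series, decode, and contrast state occupancy between conditions:

```python
import numpy as np
from restdyn import (HMMSpec, StudyManifest, compare_conditions,
                     decode_dataset, fit_vb_restarts, make_study,
                     paperlike_profile, standardize_inputs,
                     state_metrics_table)

manifest = StudyManifest(subjects=tuple(f"s{i:02d}" for i in range(1, 9)),
                         fmri_samples_per_run=150)
study = make_study(manifest, paperlike_profile(), seed=42,
                   include_eeg=False, include_voxels=False)
data = standardize_inputs(study.fmri)
model = fit_vb_restarts(data, HMMSpec(n_states=4, seed=0))
print(f"free energy: {model.free_energy_final:.1f} "
      f"after {model.free_energy_trace.size} cycles")
paths = decode_dataset(model, data)
contrasts = compare_conditions(state_metrics_table(paths))
cols = ["state", "difference", "t", "df", "p", "p_adjusted", "cohens_d"]
print(contrasts[cols].round(3).to_string(index=False))
```

Output:

```
free energy: 79670.5 after 5 cycles
 state  difference       t  df     p  p_adjusted  cohens_d
     0       0.072   3.128   7 0.017       0.067     1.106
     1      -0.238 -15.795   7 0.000       0.000    -5.584
     2       0.115   3.979   7 0.005       0.021     1.407
     3       0.051   1.447   7 0.191       0.765     0.512
```

Each row is one state's paired EO−EC contrast over the 8 subjects
(difference = EO minus EC mean fractional occupancy, df = subjects − 1,
`p_adjusted` Bonferroni-corrected over the 4 states). Fitted state labels
are arbitrary: here state 1 is the generator's EC-preferring high-alpha
state — its occupancy is 0.24 higher under EC (t(7) = −15.8, adjusted
p < 0.001), exactly the planted condition effect, while state 3 shows no
reliable difference. On real data the same call chain applies, with
`load_dataset(manifest.json)` replacing the simulation.

The full synthetic experiment — alpha features and EO/EC alpha test, both
HMMs with model selection, metrics and first-quarter contrasts, sliding
windows with cross-modal correlation, state spectra and the multi-level
GLM — runs as one command and writes a TSV/JSON report directory:

```sh
restdyn paperlike --desk-scale --seed 1 --out report/
```

Other subcommands (`simulate`, `train`, `select`, `metrics`, `windows`,
`spectra`, `glm`) expose the individual stages; all I/O is plain TSV and
JSON.

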