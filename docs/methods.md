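# Methods

`restdyn` analyses multichannel resting-state recordings as a sequence of
recurring *brain states*: a hidden Markov model (HMM) with multivariate
Gaussian observations is inferred at the group level, each run is decoded
to its most likely state path, and state dynamics are summarised and
contrasted between eyes-open (EO) and eyes-closed (EC) rest. Because the
kind of concurrent EEG–fMRI dataset this pipeline targets is rarely
shareable, the package includes a first-class synthetic study generator
with known ground truth; every downstream stage is validated against that
truth.

## The model

Observations $x_t \in \mathbb{R}^C$ (standardized network or electrode
amplitudes) are generated by a latent chain $z_t \in \{1..K\}$ with initial
distribution $\pi$, transition matrix $A$, and state-conditional emissions
$x_t \mid z_t = k \sim \mathcal{N}(\mu_k, \Sigma_k)$. A state is therefore
a pattern of mean activity plus covariance (functional connectivity)
across channels.

Inference is variational Bayes with conjugate priors:

- $\pi \sim \mathrm{Dir}(\alpha_0 \mathbf{1})$ and each row
  $A_{j\cdot} \sim \mathrm{Dir}(\alpha_0 \mathbf{1})$, $\alpha_0 = 1$;
- $(\mu_k, \Sigma_k) \sim$ Normal–Inverse-Wishart with prior mean $0$,
  mean-precision $\beta_0 = 0.1$, scale $= I_C$ and degrees of freedom
  $\nu_0 = C + 2$ (the smallest value with a finite prior covariance
  mean). On standardized inputs this is a weak, unit-scale prior.

Each cycle alternates a forward–backward E-step run with the expected
log-parameters (digamma forms) and conjugate M-step updates. The
variational free energy $F = -\log\tilde{Z} + \mathrm{KL}$ is recorded
after every E-step; by construction it is non-increasing, and the fit
stops when the relative change falls below `tol = 1e-5` (or after
`max_cycles = 500`). `free_energy(model, data)` decomposes into a
dataset-dependent bound term (additive over runs) and a
dataset-independent KL penalty.

**Group-level contract.** All runs share one state set; gamma (the
posterior state probability course) stays resolved per run. Runs are
chained with the initial distribution re-applied at every boundary, and no
transition is counted across boundaries. The k-means initialization is fit
on the lexicographically *sorted* pooled matrix and then applied to rows
in their original order, so fitted parameters cannot depend on run
concatenation order.

**Initialization and repeats.** Each fit starts from a single seeded
random-restart k-means hard assignment followed by one M-step. A single
restart is deliberate: repeat reliability (below) is only a meaningful
model-selection diagnostic when independent repeats can genuinely
disagree. Where one best fit is wanted rather than a reliability
estimate, `fit_vb_restarts` runs several derived-seed fits and keeps the
lowest free energy.

**Decoding.** The Viterbi path maximizes the joint state-sequence score
under the variational expected log-parameters (posterior point estimates,
the same scores that drive the E-step); ties break toward the lower state
index. All state metrics are computed from Viterbi paths; a
`threshold_activation` alternative (state active when gamma > 0.8) is
provided. Numerics: the forward/backward recursions normalize at every
time step (after subtracting the per-timepoint log-likelihood maximum),
which is algebraically equivalent to log-space recursions; Viterbi scores
accumulate in log space directly.

## Model selection

The inference is stochastic and does not choose $K$. `scan_states` refits
over a state-count range (2–15 in the emulated design) with several
repeats (5) and collects:

- **free energy** — decreases with every added state, so reported but
  never used as the sole criterion;
- **maximum fractional occupancy** — per run, the largest single-state
  occupancy; values near 1 mean one state dominates a run (a
  dynamics-poor model);
- **repeat reliability** — states of two repeats are matched one-to-one
  by maximizing total Pearson correlation between concatenated gamma
  courses (optimal linear assignment); the mean matched correlation
  measures inference stability. Gamma courses, not binarized paths, are
  correlated: they retain the posterior uncertainty.

`select_model` keeps the largest $K$ whose mean reliability clears a floor
(default 0.80) and, within it, the repeat with the lowest mean per-run max
occupancy. The strict rule raises when no $K$ clears the floor; the
end-to-end driver passes `fallback=True`, taking the most reliable $K$ and
recording the fallback in the rationale.

## State metrics and condition contrasts

Per run and state: fractional occupancy (FO, shares of samples, summing
to 1), lifetimes (seconds per maximal visit; boundary-truncated visits
included by default, excludable by flag), interval times (gaps between
consecutive visits of the same state), and the switching rate. The
switching rate is per sample (changes / (T−1)); a per-second column is
provided since the dimensionless value depends on the sampling grid.
Lifetimes and intervals are reported descriptively only — visit counts
differ between conditions, so their per-visit distributions do not pair.

EO-vs-EC contrasts: same-condition runs are averaged within subject, then
a two-sided paired t-test per state (df = n−1) with Bonferroni correction
across states. Cohen's d is the mean difference over the SD of the
differences (so $d = t/\sqrt{n}$); its 95% CI comes from noncentral-t
inversion. A first-quarter variant truncates each path to ⌊T/4⌋ samples
(2.5 min of a 10-min run) before the same computations, targeting the
transient dynamics right after eye closure.

## Sliding windows and cross-modal correlation

`windowed_fo` computes FO inside windows defined in *seconds* from run
start (default 10 s, zero overlap; trailing partial windows dropped), so
a 40 Hz EEG-state path and a 0.5 Hz fMRI-state path of the same run share
one window grid. Group-mean courses carry t-based 95% CI bands.
`crossmodal_correlation` correlates every fMRI-state × EEG-state pair of
group-mean courses over windows (Pearson, two-sided p from the t
transform, Bonferroni over all cells — e.g. m = 30 for 6 × 5 states).
Correlating group-mean courses (rather than averaging per-subject
correlations) follows the group-level reading; a per-subject route can be
assembled from the run-subject courses.

A caveat the validation suite respects: when a condition's occupancy is
stationary, group FO courses are near-constant and their correlation
measures estimation noise rather than shared dynamics. Cross-modal
recovery is therefore quantified on EC runs, where the generator injects
a real post-eye-closure transient, and only for states that both models
demonstrably recover (gamma-to-truth correlation > 0.7 in each modality).

## EEG alpha features

Zero-phase order-4 Butterworth bandpass at 7–13 Hz (applied
forward–backward; stopband checks are part of the test suite), polyphase
anti-aliased downsampling to 40 Hz, epoching by the TR (2 s → 80 samples
per epoch), per-epoch Welch power (Hann, 1 s segments, 50% overlap,
density summed over the band) averaged over the posterior channel set
(Oz, O1, O2, PO3, PO4, POz), and per-run z-scoring for regressor use. The
HMM input is the Hilbert envelope of the band-limited, downsampled
series. Two independent band-power estimators — envelope²/2 and Welch —
agree within 10% on in-band tones, a cross-check the acceptance suite
runs. The subject-level alpha contrast is the same paired-t engine as the
state metrics. Posterior-component selection (ICA) is bypassed: the
generator emits already-posterior channels; with real data, substitute
the retro-projected components at the `envelope_dataset` hook.

## HRF GLM mapping

The canonical double-gamma HRF, $h(t) = g(t;6,1) - \tfrac{1}{6}
g(t;16,1)$ (unit-scale gamma densities, peak-normalized, 32 s support),
has $h(0)=0$ and peaks near 5 s. State gamma courses (probabilities, not
binarized activations) are convolved causally at their native rate and
sampled at the TR instants. First-level GLMs are OLS per target with an
intercept, demeaned regressors and ± contrasts; optional single-lag AR(1)
prewhitening is available but off by default. Run betas are averaged per
subject and condition (fixed effects), and group maps come from
one-sample (or paired, for EO−EC) t-tests, Bonferroni-corrected across
targets. This parcel-level group inference is a deliberate, simpler
replacement for mixed-effects cluster inference on volumes, which is out
of scope; results are per-parcel t/p tables, not thresholded images.

## State spectra

State-wise weighted multitaper estimation: the series is cut into 2 s
windows, each gets a DPSS multitaper PSD (time-bandwidth 3, five tapers),
and state k's spectrum is the weighted average of window PSDs with
weights equal to the window-mean gamma of state k. With one state this
reduces exactly to the plain segment-averaged multitaper PSD. Per-window
weighting (rather than per-sample weighting inside the Fourier transform)
matches the "more likely active periods contribute more" semantics and
keeps the estimate inside the pointwise envelope of the window PSDs.

## Synthetic study generator

The generator emulates the targeted study design: 21 subjects (18 when a
few EEG sets are dropped), four 10-min runs each in the order EO, EC, EO,
EC; 13 named network channels on a TR = 2 s grid (300 samples per run);
6 posterior EEG channels. One latent chain per run is sampled at the EEG
raw rate and index-decimated to the TR grid, so the two modalities share
occupancy exactly at the ground-truth level.

Choices and their reasons:

- **Raw EEG rate 200 Hz**, not the acquisition-grade 5 kHz: the pipeline
  only uses content below 20 Hz, and 200 Hz keeps full studies desk-sized.
- **Chain family**: persistence-mixture transitions
  $A = p I + (1-p) \mathbf{1}\pi^\top$, whose stationary law is exactly
  $\pi$; mean dwell ≈ 6 s (p set from a dwell time in seconds and the
  grid rate), in the range of reported resting-state lifetimes.
- **Condition effects**: EC shifts the stationary occupancy toward the
  high-alpha state (0.15 → 0.30 by default) and scales EEG amplitudes by
  1.5; an optional ramp transiently boosts the high-alpha state's
  occupancy at EC onset, decaying with a 75 s time constant — the
  post-eye-closure spike that returns to baseline in roughly 2.5 min.
  The true functional form of such within-run nonstationarity is unknown;
  the exponential ramp is the simplest monotone-decay choice.
- **States**: four canonical patterns (sensory, default-mode,
  attention/salience, low-activity high-alpha with elevated visual
  covariance); EEG amplitudes differ mainly by level, which deliberately
  makes the low-alpha states hard to separate — as in real
  amplitude-defined EEG states — while the high-alpha state stands out.
- **EEG noise**: white Gaussian by default (1/f via a spectral-shaping
  flag); broadband noise structure is otherwise unconstrained.
- **Parcels**: 40 parcels with block-sparse state loadings driven through
  the double-gamma HRF plus AR(1) noise (ρ = 0.3) stand in for voxels.
- **Seeding**: every run's randomness derives from the study seed through
  `subseed(seed, subject, run, stream)` (NumPy `SeedSequence` spawn
  keys), so any single run can be regenerated in isolation and identical
  seeds give byte-identical studies.

What the generator does *not* emulate: MR gradient/ballistocardiogram
artifacts, volumetric geometry and registration, sleep staging, scanner
drift, or subject-level parameter heterogeneity beyond chain randomness.
Passing tests therefore demonstrate that the statistical machinery is
correct and well calibrated under the stated generative assumptions — not
that real EEG–fMRI data satisfy those assumptions.

## Validation experiment sizes

The validation suite (`restdyn.validation`, run by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses complete
desk-scale runs: exact-inference oracles on 100 random instances with
K ≤ 3, T ≤ 8 against exhaustive enumeration; recovery on 20 runs × 500
samples at mean separation 4 for K = 2–4; selection scans over
K ∈ {2, 3, 6} with 5 repeats on true-K = 3 data; contrast calibration and
power with 200 replicates of 20-subject studies at 100 samples per run
and a planted occupancy shift of 0.1; a shared-chain cross-modal study of
8 subjects × 300-sample runs plus a 100-replicate independent-chain null
at m = 30; a multi-level GLM recovery of 0.5σ effects planted in 10 of
200 parcels across 20 subjects; and a double execution of the reduced
end-to-end driver (4 subjects, 100-sample runs, K ∈ {2, 3} × 2 repeats)
compared byte for byte.

## Known limitations

- Gaussian emissions only; no time-delay-embedded or autoregressive
  observation models, so spectrally defined states are out of reach.
- The Markov assumption: state probabilities depend only on the previous
  sample's state; semi-Markov dwell control is not modelled.
- No cluster-extent or random-field inference; group maps are
  Bonferroni-thresholded parcel tables.
- First-level GLMs are not prewhitened by default; with strongly
  autocorrelated targets enable the AR(1) flag.
- Repeat reliability with few repeats (2) is a single correlation and
  noisy; the emulated design's 5 repeats are recommended whenever runtime
  allows.
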