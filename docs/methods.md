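# Methods

This package reimplements, on synthetic data with known ground truth, an
analysis of how auditory-cortical responses adapt to changes in background
noise: encoding models are fitted to continuous responses to speech in
switching noise, the convolutional model is linearized into time-varying
filters (dynamic STRFs), and adaptation is quantified with
transition-aligned indices and population statistics.

## Stimulus and session design

A session consists of a silent 2-minute lead-in (used to z-score responses)
followed by 18 blocks of roughly one minute each (reduced-scale runs use
fewer, shorter blocks). Within the blocks, the background switches every 3
or 6 s between four conditions: clean, and three noise classes chosen to
span spectrum and stationarity — a low-frequency speech-overlapping class
("bar"), a broadband nonstationary class ("city"), and a high-frequency
nearly stationary class ("jet"). Noisy segments mix the speech-like
foreground with the class's noise at 6 dB SNR, enforced segment-by-segment
on mean-squared bin power (realized SNR within 0.1 dB). The condition
sequence is a random walk with no immediate repeats, exposure-balanced
within 20% across conditions.

Spectrograms are generated directly in a 23-band, 100-Hz mel-like domain;
no audio is synthesized. The foreground has 2–3 formant-like peaks drifting
slowly in frequency, amplitude modulation concentrated at the syllabic
2–8 Hz range, and silent gaps under 300 ms. All downstream analysis
consumes spectrograms only.

## Ground-truth encoders

Each synthetic electrode is one of four generative mechanisms applied to a
Gabor-like base filter (65 lags = 650 ms):

- **static_linear** — r(t) = rectify(filter ∘ stimulus window). The
  rectifier is softplus by default ("linear" and "relu" are config
  switches; the *null* sessions used for index-distribution controls use
  "linear" so the encoder is exactly nonadaptive — with softplus, a real
  contrast-dependent local slope exists and the dSTRF correctly reports
  it).
- **gain_adaptive** — the rectified drive is multiplied by
  g = k·(c + c₀)^(−α), where c is the stimulus contrast (sd of all bins)
  in a trailing 1-s window, with first-order relaxation (τ_adapt). The
  softening constant c₀ = 0.1 keeps the gain finite in silence. Defaults
  k = 1, α = 0.5, τ_adapt = 0.3 s.
- **noise_filtering** — after each transition the filter is augmented
  (exponential approach, τ_adapt) by components matched to the incoming
  noise class: an inhibitory component (new inhibition at the noise's
  above-average bands, restricted to non-excitatory cells of the base
  filter) and, optionally, a mirrored excitatory component (new excitation
  at the noise's below-average bands). Components are unit-Frobenius
  normalized; depths are in base-filter-norm units (base norm 3.0, default
  depth 1.5 = half the filter's magnitude at steady state).
- **ln_stp** — rectified drive through Tsodyks–Markram resource dynamics
  (release fraction u, recovery τ_rec) and a Gompertz ("double
  exponential") output nonlinearity.

All encoders add a constant to the drive before rectification equal to 1.5
task-period drive standard deviations. This models ongoing baseline
activity and keeps the rectifier mostly in its responsive region; without
it, half the drive distribution is clipped and even the "static" encoder
is strongly nonlinear. An optional additive transient after every
transition (amplitude, τ) emulates the onset deviation-and-return that the
adaptation index measures. Observation noise is additive Gaussian at the
response stage; responses are z-scored to the silent lead-in (exactly mean
0 / variance 1 there).

The generators expose their time-varying effective filter
(`effective_filter_timecourse`), which serves as the analytic oracle for
the dSTRF-based metrics.

## Encoding models

**Ridge STRF.** Linear regression of each electrode on the lagged
spectrogram (65 lags), ridge-penalized, with the penalty chosen per
electrode by leave-one-block-out cross-validated prediction correlation.
This occupies the same regularized linear-Gaussian estimator family as
normalized reverse correlation with tolerance/sparseness sweeps; the
lambda grid plays the role of the sweep. Implemented with per-block Gram
matrices and Cholesky solves; the intercept is unpenalized (both design
and targets are centered).

**CNN.** A 1-D convolutional network: 5 layers, 128 kernels (reduced runs
use 16–32), kernel size 5, stride 1, no padding, dilations (1, 1, 2, 4, 8),
ReLU activations, no hidden biases, and a final per-electrode linear
projection (the only bias). The receptive field is
1 + Σ(k−1)·d = 65 samples. The trunk is shared; all electrodes are
predicted jointly with a mean-squared-error objective. Training uses RAdam
with decoupled weight decay 0.03, an exponential learning-rate decay of
0.996 per epoch, and early stopping on one held-out block. The base
learning rate (default 1e-3; reduced-scale runs use 3e-3) and epoch budget
are free choices. Forward, backward and the optimizer are implemented in
NumPy; gradients are exact (the network is piecewise linear), and the
finite-difference tests in the suite pin them.

Inputs are normalized per frequency band by the training-set standard
deviation (scale only); targets are used raw. This keeps the input in the
positive orthant, where the bias-free trunk's activation geometry yields
stable, interpretable input gradients — the property the dSTRF analysis
depends on. The alternative regime (per-band z-scoring plus per-electrode
target standardization, both available as options) fits equally well but,
at small training scales, through near-linear solutions whose gradients
fluctuate in stimulus directions the data barely constrain; it also
requires the target standardization, because the large baseline offset of
lead-in-normalized responses can otherwise push every hidden unit of a
bias-free trunk negative early in training, permanently killing the
gradient. The cost of the positive-orthant default is a level-dependence
of the activation pattern that contributes to the null-index bias
discussed below.

**LN + STP.** A 650-ms FIR (initialized from the ridge STRF and held
fixed — the release fraction u is not identifiable jointly with a free
drive scale, since u and the scale enter only as a product in both the
depletion and the output), Tsodyks–Markram resource dynamics, and a
Gompertz output nonlinearity; STP and nonlinearity parameters are fitted
by multi-start Nelder–Mead on MSE (≥ 5 restarts over a u × τ_rec grid).

**Jackknifing.** For each held-out test block, n_blocks − 1 members are
each trained excluding one additional block (which doubles as the member's
early-stopping validation block); test predictions are the member mean.
At full scale this is the 18-block / 17-member design; reduced runs scale
the member count with the block count.

## dSTRF extraction

For a ReLU network without hidden biases the input gradient at a stimulus
window is the exact equivalent linear filter at that instant:
Σ(dSTRF ∘ x) + output bias equals the prediction (asserted at 1e-4
relative tolerance over ≥ 1000 random network/input pairs, and exact frame
constancy under perturbations that flip no ReLU). Gradients are computed
by reverse-mode accumulation through the convolution stack — identical to
multiplying the activation-masked weight matrices. At ReLU kinks the
subgradient 0 is used (a measure-zero set). The identity is stated in the
network's normalized input space; dSTRFs are reported in raw stimulus and
response units by chain-ruling the per-band input scale and per-electrode
target scale (the input mean shift does not enter the gradient).

Per time point, member dSTRFs are averaged with a sign-consistency mask: a
lag-frequency bin is kept (at the plain member mean) only if at least
`min_agree` members give it the same strict sign, else set to exactly 0;
zeros count toward neither sign. At full scale min_agree = 15 of 17; for M
members the default is ceil(M·15/17). Masking is applied before all
gain/correlation analyses.

**Known reduced-scale artifact.** With few members the mask is effectively
all-must-agree, and mask coverage itself becomes stimulus-dependent:
post-transition (louder, spectrally richer) stimuli determine the dSTRF
better, so fewer bins are masked after a transition than before. This
inflates masked-gain changes slightly upward on null data. The suite
measures this on truly linear encoders; it shrinks with member count and
session length.

## Adaptation metrics

- Stimulus contrast: 20·log₁₀ of the sd of all time–frequency bins in a
  segment, floored at −120 dB.
- dSTRF gain at a time point: sd over all lag-frequency bins; excitatory /
  inhibitory gain zero the opposite-sign bins first (zeros stay in the
  population).
- Noise-spectrum correlation: Pearson r between the lag-averaged
  (region-zeroed) frequency profile and the incoming noise's mean
  spectrum; for transitions to clean the target is the session-average
  clean-speech spectrum (silent gaps included). Constant profiles give an
  undefined (NaN) correlation which is excluded, never zero-filled.
- Alignment: windows [−0.5, +1.15) s around transitions, at 10-ms
  resolution, transition sample owned by the post condition; gain and
  correlation time courses use only clean→noise and noise→clean
  transitions; windows not contained in their flanking segments are
  dropped.
- Indices: paired t between window values 0.5–0 s before and 0.65–1.15 s
  after the transition (50 pairs), pairing by within-window position on
  the transition-averaged time course. Positive gain-change = gain rose;
  the noise-filtering index flips the sign so positive = the filter
  steered away from the new noise. The adaptation index compares the
  response 0–0.7 s vs 2–2.7 s after a transition (70 pairs; positive =
  transient that returns to baseline), averaged over the four
  to-conditions per electrode. Zero-variance differences are capped at
  ±1e6 and flagged; windows with < 50% defined frames yield a missing
  index.

## Population statistics

Responsive electrodes: per-electrode paired t on 0.5-s windows around
speech onset, Benjamini–Hochberg corrected at q = 0.01.
Subject-controlled tests: the value vector is regressed on an intercept
plus subject indicator columns; the indicators are centered so the
intercept estimates the grand mean (with one subject this is exactly the
one-sample t). The improvement model is
improvement ~ gain index + noise-filtering index + (1 | subject), a random
intercept per subject (statsmodels MixedLM), falling back to OLS with a
flag when the random effect is singular. Clustering uses Ward linkage on
the 8 noise-filtering features (excitatory + inhibitory × 4
to-conditions), cut at k = 2, labels oriented by the mean excitatory
to-noise index. Group response comparisons use Wilcoxon rank-sum per time
point on baseline-subtracted (mean over 2–3 s post-transition)
transition-aligned responses at raw p < 0.05 (no multiplicity correction;
flagged in the report).

## What the synthetic data do and do not show

The generator produces responses whose adaptive structure (contrast gain
control, spectral noise suppression, onset transients) is known exactly,
so recovery tests demonstrate that the estimation pipeline — model fitting,
linearization, masking, alignment and indices — detects each mechanism
with the right sign and localization, and stays near null on nonadaptive
encoders. They do not establish anything about real cortical responses:
the synthetic high-gamma is a rectified filter output with Gaussian noise
(no trial variability structure, no across-electrode correlation, no
cross-frequency coupling), the foreground is not real speech, and effect
sizes are set by generator parameters rather than physiology.

## Reduced problem sizes

The default test-suite and pipeline configurations run on one CPU:
sessions of 4–6 blocks of 30–45 s, 4–20 electrodes, 16–32 kernels, and
3-member ensembles. These sizes are the package's demo-scale study
conditions; the full-scale configuration (18 × 60 s, 128 kernels, 17
members) is provided as `full_scale()`.

## Known limitations at reduced scale

Three properties of the full-scale design degrade measurably at the
one-CPU demo scale, and the test suite reports them honestly rather than
papering over them:

- **Null index inflation.** On purely linear encoders, masked dSTRF
  gain-change and noise-filtering indices have mean |t| well above the
  ideal ~0. Three mechanisms: the positive-orthant input geometry couples
  ReLU activation counts to stimulus level, so the local slope grows with
  loudness even for a linear target; with 3 members the sign mask is
  all-must-agree and its coverage is stimulus-dependent (post-transition
  stimuli determine the dSTRF better, so fewer bins are masked after a
  transition); and the position-paired t on smooth transition-averaged
  curves is strongly autocorrelated, so any small systematic shift yields
  a large |t|. These effects shrink with member count and session length
  but do not vanish at demo scale.
- **Improvement localization and clustering.** The CNN's improvement over
  the STRF on noise-suppressing encoders is robustly positive but not
  larger inside the 650-ms post-transition window: in this generator,
  adaptation is a deterministic exponential (tau 0.3 s) largely complete
  within the window while the model's receptive field still straddles the
  boundary, so the CNN's advantage comes from condition-dependent
  steady-state filters. Likewise, per-class excitatory noise-filtering
  features rest on ~3 transitions per class at demo scale and estimation
  blur spreads inhibitory suppression into the estimated excitatory
  region, making Ward recovery of the two planted populations unstable
  (0.5–0.95 agreement across seeds). The adaptation-index ordering of the
  two populations is recovered regardless.

## Numerical choices

Half-open [start, end) windows everywhere at 10-ms sample resolution.
Ridge lambda grid 10⁰…10⁵, per-electrode argmax of cross-validated
correlation. CNN weights He-initialized from a seeded generator; chunked
(~15 s) minibatches in shuffled order; runs are bit-reproducible given the
seed. Degenerate cases: zero-power backgrounds raise; constant segments
floor at −120 dB; undefined correlations propagate as NaN with a ≥ 50%
coverage rule; baseline z-scoring falls back to centering when the
baseline is constant (noiseless simulations).
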