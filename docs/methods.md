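# Methods note

This note documents the models, parameterizations and numerical choices
implemented in `loombias`. It describes what the code computes; no
empirical claims are made beyond what the package itself computes on
synthetic data.

## Spectral-contrast manipulation (`loombias.hrtf`)

Directional transfer functions are represented as dB magnitude spectra per
direction and ear. The contrast operation maps each in-band magnitude
M(f) to

    M_C(f) = C · M(f) + (1 − C) · Σ_k w′(k) M(k) / N_f,

i.e. a linear rescaling about the weighted in-band mean, restricted to the
analysis band (default 1–16 kHz); out-of-band bins are untouched. The
weights w′(f) are proportional to 1/ERB(f) with
ERB(f) = 24.7 (4.37 f/1000 + 1) and normalized to mean 1 over the band, so
the operation conserves the ERB-weighted in-band mean exactly (machine
precision) for every C. Useful consequences, all tested: identity at C = 1
(bit-exact), zero in-band variance at C = 0, exact anti-correlation at
C = −1, linearity in the input spectrum, and composition
(apply C₁ then C₂ ⇔ apply C₁·C₂).

Optional smoothing uses a row-stochastic gammatone-magnitude kernel,
[1 + ((f − f_c)/b)²]⁻² with equivalent rectangular width equal to a
configurable multiple of ERB(f_c) (b = 2·ERW/π); rows are renormalized to
sum to 1 so constant spectra are preserved.

## Stimuli (`loombias.stimuli`)

Harmonic complexes contain the harmonics of f₀ inside the band with equal
amplitudes and Schroeder-type phases φ_n = c·π·n(n+1)/N (curvature c,
N components), which lowers the crest factor relative to sine phase.
Spatialization interpolates the direction's magnitude spectrum onto an
FFT grid and renders a minimum-phase FIR via the folded real cepstrum;
magnitude-only filtering discards interaural time differences, so an
optional integer-sample ITD can be reinstated. Looming/receding trials
crossfade two spatializations of the same source with complementary
raised-cosine ramps (10 ms) at an onset jittered uniformly in
600 ± 50 ms; with identical endpoints the transition is exactly invisible.
RMS equalization applies one scale factor per stimulus (both channels),
preserving interaural level relations.

## Localization scoring (`loombias.localization`)

Directions use interaural coordinates: lateral ∈ [−90°, 90°], polar ∈
[−90°, 270°). Per trial the lateral error is |Δlateral| and the polar
error the circular difference in [0°, 180°]. Polar errors above 90° count
as quadrant errors (front/back or up/down confusions) and are excluded
from the local polar error, which is therefore NaN if every trial is
confused. Chance references come from a virtual experiment: targets are
resampled with replacement and responses drawn from a configurable
sampler (default: uniform over the rectangle spanned by the target
range); observed/chance ratios are ≈1 at chance and 0 for perfect
performance. For uniform lateral targets and responses on [−90°, 90°] the
analytic chance lateral error is span/3 = 60°.

## ERP cluster statistics (`loombias.erp`)

Paired condition contrasts are tested with a nonparametric spatiotemporal
cluster-based permutation test. Per (channel, time) sample a dependent-
samples t value is computed across participants; samples exceeding the
two-tailed threshold t_{1−α/2, n−1} are connected through same-channel
temporal adjacency and same-time spatial neighborhood (distance-based
adjacency), with opposite polarities never merging. The cluster mass is
the summed t. The null distribution flips the sign of each participant's
difference map (equivalent to swapping conditions within participants)
and records the maximum cluster mass separately per polarity; observed
clusters are compared against the matching-polarity null with
p = (b + 1)/(n_perm + 1), doubled for two-tailedness and capped at 1.
Keeping the polarity-specific nulls (rather than a pooled max-|mass|
null combined with doubling) is what makes the single-sample reduction
agree with a standard sign-flip permutation t-test, and calibrates the
family-wise type-I rate to ≈ α; this is verified in the acceptance suite.

Blind trial-count equalization retains min(counts) trials per condition,
removing positions floor((i + 0.5)·n/r), i = 0..r−1 — as evenly spaced
over the session as possible and independent of the data. Cluster scores
for single-trial modelling average each trial over the cluster's
[t_min, t_max] epoch and every channel that contributed to it.

## Linear ballistic accumulator (`loombias.lba`)

Two accumulators (looming, receding) race linearly from uniform start
points on [0, A] to threshold b = A + B with normal drift rates (mean v,
SD s_v = 1, truncated to positive values by dividing density and CDF by
Φ(v/s_v)). The standard closed forms give each node's first-passage
density and CDF; a dedicated A → 0 branch uses the passage-time limit
b/drift. The defective density of (choice, RT) is
f_winner · Π (1 − F_loser), which integrates to 1 over choices and time
under the truncation convention. The first-passage tail decays like 1/t²
(drifts near zero), so normalization checks integrate to infinity
(`scipy.integrate.quad` with an infinite limit), not to a finite horizon.

Drift means follow a regression over condition factors expanded per
accumulator: the `match` factor codes accumulator–stimulus congruency (a
flattened-to-shaped transition matches the looming accumulator), so the
model matrix differs between the two accumulators of a trial. The full
design `match*direction*cue + vertical*horizontal + eeg` yields 12
columns; rank deficiency is rejected at build time. The `eeg` term is a
continuous single-trial amplitude.

Hierarchical estimation uses adaptive Metropolis-within-Gibbs: per
subject, the joint block [log A, log B, log t₀, β…] is updated with
random-walk proposals whose scalar scale is tuned toward ~25% acceptance
and whose shape is the empirical covariance of the burn-in history
(Cholesky proposals installed after 150 burn-in iterations, scale reset
to 2.38/√P); group means use conjugate normal updates and group variances
conjugate inverse-gamma updates (a₀ = 2, b₀ = 0.1). The EEG covariate is
z-scored within subject before fitting for well-conditioned sampling; the
raw-scale slope in 1/(µV·s) is recovered per posterior draw by dividing
each subject's coefficient by that subject's amplitude SD and averaging.
In prior-only mode the posterior equals the prior and is drawn i.i.d.
directly, which the prior-to-posterior contraction diagnostic (≈0 there)
relies on. Convergence is monitored with split R̂ per group-level
parameter; the start-point/threshold scale (log A vs log B) is weakly
identified and mixes slowest, while drift-rate coefficients — the
quantities of scientific interest — converge quickly. Model comparison
uses BPIC = D̄ + 2p_D (p_D = D̄ − D(θ̄)) and BIC-difference Bayes factors
BF = exp(ΔBIC/2).

## Synthetic generator (`loombias.synth`)

The generator emulates the statistical structure the analysis assumes, at
the scale of the mirrored experiment: 14 subjects, 8 blocks × 100 trials
(blocks alternating native/novel cues, 50/50 flattened/shaped within
block), four positions (polar 45°, 135°, 225°, 270°), group drift
contrast 0.36 s⁻¹ and EEG drift slope −0.017 (µV·s)⁻¹ by default.
Subject parameters vary log-normally (A, B, t₀) or normally (drift
coefficients). Single-trial EEG amplitudes are condition means
(±contrast/2, polarity reversing between native and novel cues) plus
Gaussian noise; behavior is simulated from the LBA forward model with the
amplitude term included, so EEG and behavior are dependent exactly as the
joint model assumes. ERP epochs add a condition-signed (or
amplitude-linked) effect in a configurable window (default 80–170 ms) on
a set of adjacent channels over spatially correlated noise (exponential
covariance decay with electrode distance). Localization responses follow
gain·target + bias + scatter with a configurable probability of quadrant
confusion redrawn near 180° (rear bias). All randomness flows from one
master seed through named substreams; bundles regenerate bit-identically.

## Limitations

- The sampler is a random-walk scheme, not a particle-based or gradient
  sampler; structural LBA parameters (start-point and threshold scale)
  carry wide, slowly mixing posteriors at desk-scale chain lengths. Drift
  coefficients and their contrasts are well behaved.
- The ERP generator is phenomenological: no biophysical forward model, no
  continuous raw EEG, epochs only.
- SOFA support is read-only and assumes the binaural SimpleFreeFieldHRIR
  layout; writing manipulated spectra uses plain CSV tables.
- Single-trial amplitude variance and ERP noise parameters are
  configuration defaults chosen for reasonable statistical power at
  experiment scale, not empirical estimates.
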