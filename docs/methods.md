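# Methods

This note documents the models, algorithms and numerical choices behind
`betalat`: what the synthetic data emulate, how each analysis stage is
computed, which defaults were chosen where the design was open, and what
the passing tests do and do not establish about real data.

## Stimulus schedules

A sequence is the union of a slow stream (3 tones, SOA 0.8 s) and a fast
stream (4 tones, SOA 0.6 s) whose first tones coincide; the sequence period
is 2.4 s and the merged sequence has 6 distinct onsets. A deviant shifts
exactly one tone 90 ms earlier and leaves every later onset at its nominal
time; this keeps the block-level 2.4-s lattice intact. Deviants are barred
from the shared first beat, leaving 5 eligible merged positions, of which 3
lie in the fast and 2 in the slow stream — this asymmetry alone produces
the attended/unattended deviant splits per block (4/6 attend-slow vs 6/4
attend-fast in high-predictability blocks; 10/15 vs 15/10 in low), the
session totals of 20 (high) + 50 (low) = 70 attended deviants, and it is
asserted rather than hard-coded.

Blocks hold 50 regular sequences plus 10 (high predictability) or 25 (low)
irregular ones, deviant positions balanced (2 or 5 per eligible tone).
Irregular placement draws distinct "gaps" before the regular sequences,
which realizes uniform placement under the constraint of at least one
regular sequence between irregulars and forces the block to end regular.
A consequence used throughout: excluding every regular sequence whose
predecessor contains a deviant retains exactly 50 − n_irregular sequences
(40 high / 25 low), deterministically. Warm-up sequences are not generated
(they are never analyzed), and printed block durations are treated as
descriptive. Audio is never synthesized; tone identity (220 Hz fundamental,
3 harmonics, 50 ms, 7 ms ramps) is design metadata only.

## Synthetic EEG

Epochs span −1.0 to 3.5 s around the onset of each retained regular
sequence (64-channel 10–20 template, 512 Hz nominal; both reducible for
small runs). Per channel,

    x_c(t) = n_c(t) + sqrt(g_c(t)) * b_c(t),
    g_c(t) = 1 + s_c * d * (1 + m * cos(2*pi*f_att*t + phi)),

with `n_c` 1/f-shaped background noise (exponent 1 by default), `b_c` an
independent 14–24 Hz Gaussian carrier scaled so its variance is `snr` times
the background variance inside the band, `s_c` ∈ {+1, −1, 0} for
ipsilateral/contralateral/midline channels relative to the attended ear,
`d` the lateralization depth, `m` the tempo-modulation depth at the
attended stream's rate `f_att`, and `phi` the planted phase. A stochastic
carrier, not a sinusoid, carries the effect, so power — not phase-locked
evoked activity — is modulated. With d = m = 0 the hemispheres are
exchangeable by construction. Optional components: unlateralized alpha-band
noise and a lateralized broadband >30 Hz component (`contamination_gain`,
default 0) emulating muscle contamination; no gamma-specific inference is
built on it. Validity constraint: d(1 + m) ≤ 1 keeps power gains positive.

Defaults (chosen once; the design literature reports no signal parameters):
d = 0.3, m = 0.6, phi = π (attended-tempo phases cluster near 180° in the
reference results), snr = 1, noise exponent 1. `phase_jitter_sd`
(default 0) adds per-subject Gaussian jitter around `phi`; the high-SNR
preset uses 0.6 rad so that group-level attended resultant lengths fall in
a realistic range rather than saturating near 1 (reported group statistics
imply R̄ ≈ 0.45 at n = 26). The preset also uses snr = 0.5: with a
noise-free LI, the attended-tempo modulation leaks deterministically into
the unattended frequency bin of the 2.2-s analysis window (≈10% amplitude),
and only a realistic noise floor reproduces the empirical pattern of
*inconsistent* unattended phases.

Behavioral responses: each deviant is answered with per-ear probabilities
(attended 0.8, unattended 0.15 by default), response times 0.2 s plus an
exponential tail truncated to the 2-s window; false alarms occur per
sequence with probability 0.02 at a uniform time. Musical-experience
covariates are drawn from N(66, 17.6²) clipped to the instrument's 18–126
range.

## Analysis stages

**Time-frequency.** 7-cycle Morlet wavelets (MNE) at full sampling
resolution, sampled onto a fixed 0.5 Hz / 50 ms grid independent of the
sampling rate. Bins where the wavelet's ±3 temporal standard deviations
(σ_t = cycles / 2πf) cross the epoch edge are invalidated (NaN + mask),
never zero-filled — zeros would bias the ratio indices. Wavelets are
energy-normalized; power is in arbitrary units because every downstream
index is a ratio.

**AMI and ROIs.** AMI is computed on condition-mean power (ratio of means,
matching its use on trial-averaged data). Channel selection uses the
presequence window [−0.2, 0) — half-open, so it shares no grid bin with
the analysis window [0, 2.2] — and a paired cluster-based permutation test:
per-channel paired t, two-sided cluster-forming threshold at α = 0.05,
neighbour-connected sign-consistent clusters (neighbourhood: 2-D Euclidean
distance threshold tuned to a median degree of ≈6), max-|cluster-mass|
null over per-subject label swaps, Monte-Carlo p = (b+1)/(n+1). "First"
cluster means largest mass per sign; the ROI size is the rounded (half-up)
mean of the first positive and first negative cluster sizes, with a
fallback of 10. Group ROIs take the k most positive left-hemisphere and k
most negative right-hemisphere channels of the group-mean presequence AMI
(midline excluded; name-ordered tie-break for determinism).

**rmANOVA and Bayes factors.** Classical two-way within-subject
sums-of-squares decomposition; each effect is tested against its own
subject-by-effect interaction. ω² = df(MS_eff − MS_err)/(SS_total +
MS_subjects), reported raw and clipped only for the verbal label
(>0.14 large, 0.06–0.14 medium, 0.01–0.06 small). Bayes factors use the
BIC approximation BF10 = exp(ΔBIC/2) comparing the interaction model with
the main-effects model (both with subject dummies); they are prior-free,
reproducible, and deliberately *not* comparable numerically with
default-prior ANOVA Bayes factors — only the evidence bands are.

**Time-resolved LI.** High/low-predictability trials are pooled (trial
count and phase-sensitivity considerations). Trial-mean ipsi- and
contralateral ROI beta power are smoothed with a 250-ms centered moving
average (5 bins; shrinking windows at edges, no invented padding) *before*
the LI ratio; the analysis works on a margin around 0–2.2 s so the
smoother never touches invalid epoch-edge bins. Ipsi/contra assignment
follows the attended ear; the two ear conditions are averaged per
attended-tempo condition before the ratio. Individual ROIs (same k as the
group ROIs) are selected from each subject's grand-average 0–2.2 s AMI,
conditions pooled. The presequence window is deliberately *not* used here:
wavelet power is autocorrelated across the window boundary, so selecting
on [−0.2, 0) imprints an onset-locked transient (~0.3 s) on the null LI
that all subjects share, biasing the phase battery; a time-averaged
selection basis makes any selection bias time-constant, and the FFT
demeaning removes it. The trade-off — individual ROI selection is no
longer disjoint from the LI data — affects the LI *level*, which the phase
analysis never uses.

**Phase extraction and circular statistics.** The LI series is demeaned
and zero-padded to a 120-s record: the resulting 1/120 Hz ≈ 0.0083 Hz grid
is finer than 0.01 Hz and holds both tempo frequencies exactly (150 × and
200 × 1/120 Hz); "1.66 Hz" is implemented as 5/3 Hz exactly. Phase is the
DFT angle at the nearest grid frequency, referenced to sequence onset;
this equals the direct complex-exponential projection of the demeaned
series by construction. A pure on-frequency cosine carries ≈0.058 rad of
irreducible rectangular-window leakage (negative-frequency component over
2.75 cycles) — a property of the estimator, not an implementation error.
Labels: attend-slow marks 1.25 Hz attended and 5/3 Hz unattended;
attend-fast the reverse.

Rayleigh tests use Z = nR̄² with the standard finite-n corrected p
(exp(√(1+4n+4(n²−R²)) − (1+2n))), validated against an independent
implementation. The Harrison–Kanji two-factor circular ANOVA follows the
published toolbox scheme: resultant-based SS decomposition; for pooled
von Mises concentration κ ≥ 2, F ratios against the residual with the
correction 1/(1 − 1/(5κ) − 1/(10κ²)); for κ < 2, χ² statistics scaled by
2/(1 − r̄²), with df 2(p−1) for main effects and (p−1)(q−1) for the
interaction. The low-κ interaction statistic is referred to (p−1)(q−1) df
by field convention although its null distribution is closer to χ² with
twice those df; it is therefore mildly anticonservative (~14% at α = .05
in our null simulations), which the tests acknowledge explicitly.
κ is estimated from the pooled resultant length (Fisher's approximation
with the small-n correction). The resultant-difference permutation test is
one-sided (directional hypothesis: attended frequency more consistent),
swapping frequency labels within subjects, p = (b+1)/(n+1).

**Associations.** Attention-modulation strength = left-ROI minus right-ROI
mean AMI. Correlations with behavioral measures are one-tailed in the
hypothesized directions (hits +, SE −, RE −, TDR +). The RE regression
uses Huber-loss IRLS (statsmodels RLM, default tuning constant); R² is
computed from the final robust weights and F = R²(n−2)/(1−R²). Subjects
with |z| > 3 on the full-sample modulation-strength distribution are
excluded first; zero variance excludes nobody.

## Pipeline, seeds, problem sizes

One root `SeedSequence` is spawned per subject and per analysis stage, so
runs are byte-reproducible under a fixed seed; artifacts (schedule TSVs,
an epochs container — a zip of `.npy` arrays plus a JSON metadata block —
feature JSON, result TSVs, a manifest with a parameter hash) are written
per stage, and downstream stages can start from cached artifacts.

Simulation-heavy validations use reduced problem sizes chosen as the
smallest that keep the statistics interpretable: null calibration runs 400
pipeline datasets of 8 subjects each (200 Hz, 16-channel balanced layout
subset, 2 epochs per block, 2-Hz beta grid); recovery and the headline
pattern use 20 group runs of 20 subjects on a 28-channel subset supporting
10-channel ROIs. The full 64-channel / 512 Hz / all-trials configuration
is the default for interactive use.

## What the tests do and do not show

The generator produces stationary Gaussian-mixture signals with an exactly
sinusoidal power modulation and hemispherically symmetric noise. It does
not emulate volume conduction, evoked responses to the tones, non-Gaussian
or bursty beta dynamics, artifacts (blinks, muscle beyond the optional
broadband term), inter-channel noise correlation, or drop-out. Passing
null-calibration and recovery tests therefore establishes that the
*analysis code* is unbiased and recovers planted parameters under the
stated model — not that the scientific claims hold in human data, nor that
the pipeline is robust to realistic artifact structure. Group-level
statistics printed by examples are not expected to match any published
values numerically; only the qualitative effect structure is comparable.

## Known limitations

- The Harrison–Kanji low-κ interaction term over-rejects under the null
  (see above); interpret its significance conservatively.
- The FFT window (0–2.2 s, rectangular) leaks ~10% of an attended-tempo
  modulation into the other tempo's bin; at very high SNR this makes
  "unattended" phases look consistent. This is shared by any analysis of
  this window length and motivates the moderate-SNR presets.
- BIC Bayes factors approximate unit-information-prior model comparison;
  evidence labels, not magnitudes, are meaningful.
- The cluster-permutation null uses sign flips of subject differences,
  which assumes exchangeability of the two conditions within subject.
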