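# Methods

`chtlm` implements a cross-subject heterogeneous transfer-learning pipeline
for classifying motor imagery (MI) versus rest from functional near-infrared
spectroscopy (fNIRS), using labelled EEG motor-imagery data as the source
domain.  This note documents the models, the numerical choices, what the
synthetic generators do and do not emulate, and the problem sizes the test
harness runs at.

## Pipeline overview

1. **Preprocessing.**  Raw dual-wavelength optical intensities (730/850 nm,
   16 channels, 11 Hz) are converted to ΔHbO₂/ΔHbR with the modified
   Beer–Lambert law, band-pass filtered to 0.01–0.2 Hz, and segmented into
   10 s MI and rest windows.  Each fNIRS trial becomes a multi-plane
   continuous-wavelet scalogram image (one plane per channel and
   chromophore, 2x16 = 32 planes); each EEG trial becomes a multi-plane STFT
   spectrogram restricted to 4–40 Hz.
2. **Encoders.**  Residual CNNs with taps at the four stage outputs:
   a deeper source encoder (ResNet-34 topology) trained on EEG spectrograms,
   a lighter target encoder (ResNet-18) for fNIRS scalograms.  `tiny18` /
   `tiny34` variants (stage widths 8/16/32/64, light stem) are structurally
   identical scaled-down encoders for desk-scale experiments.
3. **Adaptive feature matching.**  During target training, candidate
   (source stage k, target stage d) pairs with k ≥ d each carry a small
   fully connected weight network that maps the spatially pooled source map
   to one nonnegative weight per source channel (softplus, normalized to
   mean 1), and a learnable 1x1-conv channel aligner (target→source
   channels).  The matching loss is the weighted per-source-channel squared
   distance between L2-normalized maps (the source map bilinearly resized to
   the target stage's spatial size).  Total loss: cross-entropy +
   β · Σ_pairs matching loss, minimized jointly over target encoder, weight
   nets and aligners; the source encoder is frozen (verified by hashing).
4. **Per-kernel deep features.**  Every main-path convolution kernel of the
   trained target encoder contributes one feature: the spatial mean of its
   activation map (taken after the convolution's batch norm, and after the
   ReLU where one directly follows).  Shortcut 1x1 convolutions are not
   feature extractors; under this convention ResNet-18 yields exactly 3,904
   features and `tiny18` yields 248.
5. **Screening.**  Two-sided Mann–Whitney U test per feature between MI and
   rest trials of the *training fold only*; features with p < α (default
   0.05, uncorrected) are kept.  If nothing passes, the 32 smallest-p
   features are used so the classifier always has inputs.
6. **SBELM classifier.**  A single-hidden-layer network with fixed random
   weights (U(−1,1), sigmoid units, width L) and sparse output weights:
   the MAP estimate under a Gaussian likelihood and Laplace prior,
   β̂ = argmin ½‖Hβ−ỹ‖² + λ‖β‖₁ with ỹ ∈ {−1,+1}, solved by cyclic
   coordinate descent (tolerance 1e-8, warm-started along a descending λ
   grid expressed as fractions of λ_max = ‖Hᵀỹ‖_∞).  λ is selected by a
   generalized-cross-validation score RSS/(n(1−df/n)²) with df = number of
   active coefficients — a leave-one-out-approximated squared error.
   `plain_elm` mode pins λ ≈ 0 (ridge-stabilized least squares), the
   ordinary-ELM ablation.  Decision rule: MI iff Hβ > 0; a score of exactly
   0 predicts rest.
7. **Evaluation.**  Leave-one-subject-out cross-validation: transfer
   training, screening and classifier fitting see only the training
   subjects; the held-out subject is scored once.  Metrics: accuracy, AUC
   (Mann–Whitney rank statistic, ties credited ½ — identical to trapezoidal
   ROC integration), recall, precision, F1, with MI as the positive class.
   The summary row is the unweighted mean over subjects; a fold with
   single-class test data has no AUC and is excluded from the AUC mean with
   a warning.

## Design choices where the design was open

* **Matching-loss geometry.**  The weighted loss indexes weights by *source*
  channels, so the per-channel comparison must live in source-channel space:
  the target map is channel-aligned (1x1 conv, C_t → C_s) and the source map
  spatially resized.  Normalizing each (sample, channel) map to unit L2 norm
  decouples β from activation scale; weight normalization to mean 1 (rather
  than softmax-to-sum-1) keeps β's meaning independent of channel count.
* **Single-loop optimization.**  Target, weight nets and aligners are
  trained jointly by SGD (momentum 0.9, cosine-decayed learning rate) rather
  than by bilevel meta-optimization: at desk scale the joint dynamics
  already drive weights away from unmatchable (noise) source channels and
  toward channels the target can both match and exploit, which is the
  behavior the weighted loss exists to produce, and the procedure is simple
  and deterministic.
* **Cross-modal input to the source encoder.**  The frozen source encoder
  expects EEG-spectrogram planes; fNIRS scalograms have a different plane
  count.  A fixed (non-learnable) linear interpolation across the plane
  index maps target images to the source's input width.  It preserves
  spatial structure, adds no trainable parameters to the frozen path, and
  makes the source features a deterministic function of the target images.
* **Candidate pairs.**  All (k, d) with k ≥ d — deeper source stages may
  inform equal-or-shallower target stages (coarse-to-fine transfer); 10
  pairs for 4-stage encoders.
* **Screening inside the fold.**  Feature selection is part of the fitted
  model; computing it on all data would leak the held-out subject's labels.
  No multiple-testing correction is applied (α is a screening knob, not an
  inference claim); this is configurable.
* **Degenerate normalization.**  A constant scalogram/spectrogram plane
  (max = min) is defined as all zeros rather than 0/0.
* **Wavelet transform.**  The scalograms use an analytic complex-Morlet CWT
  (`cmor1.5-1.0` parameterization) computed in the frequency domain,
  vectorized over channels and scales, with zero-padding past the widest
  wavelet's support (capped at 7x the record length — scales wider than the
  whole record are edge-dominated regardless).  Scales are chosen so
  pseudo-frequencies log-span the 0.01–0.2 Hz analysis band.  The tests
  verify scale calibration and time-profile agreement against PyWavelets in
  the regime where both are valid.
* **Filter realization.**  4th-order Butterworth applied forward-backward
  (zero phase), so hemodynamic latency is not distorted.  Steady-state gains
  are measured by least-squares sinusoid fits over the central half of a
  200 s record, excluding filtfilt edge transients.
* **Default constants.**  DPF 6.0 at both wavelengths, source-detector
  separation 30 mm, extinction coefficients from standard tables (all
  configurable); baseline intensity I₀ = mean over the initial 10 s rest
  unless a known baseline is supplied.

## Synthetic data: what it emulates, and what it does not

The generators stand in for two cohorts:

* **fNIRS target subjects** — 10 MI + 10 rest trials (configurable), 16
  channels at 11 Hz, 15 s task windows.  MI trials carry a canonical
  double-gamma-HRF-convolved boxcar (peak 6 s, undershoot 16 s, ratio 1/6)
  on the "contralateral" half of the channels; HbR = −0.3 x HbO₂.  All
  trials ride on 1/f noise plus a Mayer-wave sinusoid at 0.095–0.105 Hz with
  amplitude 0.5 x noise SD — realistic interference just inside the analysis
  passband.  The HRF response is normalized to unit peak, so `effect_amp` is
  the single-trial contrast-to-noise ratio when `noise_sd` is 1 (the
  default).  `effect_amp` = 1 is a realistic single-trial CNR for motor
  fNIRS; the separable regime used for sanity checks sets it to 2.
* **Inter-subject variability** — each subject draws a multiplicative
  response gain ~ LogNormal(0, 0.4) and an HRF onset latency shift
  ~ N(0, 1.5 s).  These defaults are deliberately large: high inter-subject
  variability in stroke cohorts is precisely the regime cross-subject
  transfer exists for, and with weaker variability a plain cross-subject
  model is already near ceiling and transfer has nothing to add.
* **EEG source subjects** — 22 channels at 250 Hz, 4 s trials; each class
  (left/right hand by default, up to four classes) boosts mu-band (8–13 Hz)
  oscillatory amplitude on its own channel group over 1/f background — the
  spatial band-power structure that motor-imagery EEG classifiers exploit.

Not emulated: photon-migration forward optics, motion artifacts,
short-channel physiology, EEG–fNIRS co-registration, and any claim about
real patient physiology.  Passing tests therefore demonstrate that the
*pipeline machinery* behaves as specified (recovers known structure, stays
at chance on null data, benefits from a related source domain under high
subject variability) — not that any particular clinical accuracy would be
attained on real recordings.

## Problem sizes of the test harness

The `desk_config` profile runs the full pipeline in seconds per fold: tiny
encoders on 24x24 images (14 wavelet scales), 8 transfer epochs, 12 source
epochs, SBELM width 100, batch 16.  The paired transfer-vs-ablation
experiment uses the cohort the study design prescribes — 8 subjects, 8
trials per class — at `effect_amp` 0.5, which sits on the rising part of
the difficulty curve (no-transfer LOO accuracy ≈ 0.65–0.94 across seeds);
at `effect_amp` ≥ 1 the synthetic task saturates and both arms converge to
ceiling, leaving nothing to compare.  End-to-end sanity checks use
`effect_amp` 2 (separable) and 0 (null).  Per-fold seeds are derived as
`seed + fold index`; identical configuration and seed reproduce results
bit-for-bit.

## Known limitations

* The matching loss form and the SBELM estimator are principled
  reconstructions of the cited mechanisms (learned per-map transfer weights
  inside a feature-matching distillation loss; L1-constrained Bayesian ELM
  as its MAP estimate).  A full evidence-maximization treatment of the
  posterior over output weights is left as an extension hook.
* Gradient computation is a compact numpy reverse-mode engine; it is exact
  but not fast on large images.  The full ResNet-18/34 variants at 224x224
  are functional and tested for architecture correctness, yet routine use at
  that scale is not the target of this implementation.
* The GDF reader for public EEG datasets is feature-gated on `mne`.
* AUC for a single-class test fold is undefined and excluded from means.
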