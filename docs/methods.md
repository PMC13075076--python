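# Methods

## Problem setting

Imagined tongue movements modulate sensorimotor rhythms over the
frontal–central cortex: during motor imagery the 10–12 Hz alpha/mu
rhythm desynchronizes (loses power) relative to a pre-trial baseline,
contralaterally for lateralized gestures and bilaterally for vertical
ones. The pipeline quantifies this event-related desynchronization
(ERD) per channel and uses the resulting 14-dimensional per-trial
vector to decode which of six imagined tongue actions the subject
performed.

## Data model and conventions

* Montage: the fixed 14-channel 10–20 set AF3 … O2 (consumer-headset
  layout), mastoid (M1/M2) referenced. Channel order is a frozen
  contract: feature column *j* is always montage label *j*.
* Time: 0-based sample indices, half-open epochs `[start, end)`;
  seconds appear only at API boundaries. A 5 s epoch at 256 Hz is
  exactly 1280 samples, so a 15 s trial has phase onsets 0/1280/2560.
* Units: µV for signals, µV²/Hz for spectra, percent (0–100) for
  accuracy and ERD in every report; fractions internally.
* ERD sign: `(P_baseline − P_imagery)/P_baseline × 100`; positive =
  desynchronization. This is the negative of the classic
  Pfurtscheller ERD sign; the bound ERD ≤ 100 holds with equality only
  at zero imagery power.

## Synthetic study generator

The generator emulates the offline study design the analysis assumes
(15 subjects, 3 patterns × 2 sessions × 24 trials, baseline/execution/
imagery of 5 s each) with four additive per-channel processes:

| component        | model                                   | default |
|------------------|------------------------------------------|---------|
| background       | 1/f^α-shaped Gaussian noise, α = 1       | 4 µV RMS |
| alpha rhythm     | white noise band-limited to 10–12 Hz (zero-phase Butterworth, 4 s synthesis margins cropped so the kept segment is stationary) | 10 µV RMS (×1.5 at O1/O2), CV 0.2 across channels/subjects |
| line interference| 50 Hz sinusoid, random phase per trial   | 2 µV |
| sensor noise     | white Gaussian                           | 1 µV RMS |

ERD is amplitude modulation of the alpha process: during execution and
imagery, channel *i* is scaled by `sqrt(1 − w_i g E/100)` where `w_i`
is the command's topography weight, `g` the subject's effect gain and
`E` the nominal ERD percent, so alpha *power* drops by exactly the
configured fraction (clipped at full suppression with a warning).

Topographies encode the qualitative spatial findings for tongue MI:
left-side imagery peaks contralaterally at FC6 with the ordering
FC6 > F4 > AF4 > others, right-side mirrors onto FC5/F3/AF3;
cheek-bulge maps equal the corner maps scaled by 1.15 (element-wise ≥,
reflecting stronger imagined effort); the vertical lip tasks are
bilateral over FC5/FC6/F3/F4, with the lower-lip map broader and a
`lu_ld_overlap` knob (default 0.3) mixing the upper-lip template into
it. Nominal ERD magnitudes default to corner 30 %, cheek 40 %, upper
lip 35 %, lower lip 25 % — free parameters chosen once to reproduce
the observed ordering (cheek > corner, lower lip weakest-discriminable
through its overlap with the upper-lip map); they are configuration,
not claims about physiology.

Inter-subject variability — the dominant characteristic of real MI
data — enters through per-subject lognormal amplitude draws, a normal
effect gain (SD 0.2, truncated at 0) and per-channel multiplicative
topography jitter (SD 0.1, clipped at weight bounds). All draws hang
off one master seed via `numpy` seed sequences keyed by subject id, so
a study is reproducible end-to-end and any subject/trial can be
regenerated in isolation.

What the generator deliberately does **not** model: volume conduction /
dipole forward fields, ocular or muscle artifacts, glossokinetic
potentials, non-stationary drift across a session, or realistic
cross-channel covariance beyond the shared line phase. Passing tests
therefore demonstrate that the *analysis chain* is correct and
calibrated, not that real tongue-MI EEG reaches any particular
accuracy.

## Preprocessing

50 Hz notch (2 Hz-wide FIR band-stop, 845 taps) then 2–40 Hz bandpass
(windowed-sinc Hamming FIR, 423 taps ≈ 2 Hz transition at 256 Hz),
both applied zero-phase by running the symmetric kernel forward and
backward via FFT convolution with reflection padding — the same
response as filtfilt at a fraction of the cost. Filtering precedes
segmentation so edge transients stay outside the 5 s epochs; epochs
shorter than 3× the kernel are rejected. Measured responses: ≥ 60 dB
at 50 Hz and at DC/≥45 Hz, ≤ 0.01 dB across 8–30 Hz. All 14 channels
are kept by default (they are all part of the feature definition); a
config option restricts to a frontal–central subset, preserved in
montage order.

## Spectral estimation and features

Welch's averaged modified periodogram with 1 s **symmetric** Hamming
windows (the classical taper; note scipy's string spec would give the
periodic variant), 50 % overlap, 256-point FFT and per-window mean
removal — nine windows per 5 s segment, 1 Hz grid. Band power is the
*mean* density over bins with both edges inclusive (alpha = bins 10,
11, 12). A 1 s input degenerates to a single periodogram, which the
tests exploit as an independent DFT oracle.

Two topographic summaries are provided, because they answer different
questions:

* `grand_average_topography` — channel-wise mean of per-trial ERD
  values from a feature matrix (the map a feature-level analysis
  draws).
* `grand_average_erd` — ERD of across-trial *power* means from epochs.
  The per-trial ratio has a heavy left tail (trials whose 9-window
  baseline estimate happens to be small produce ERD values like
  −500 %), which biases its mean several points low; averaging power
  first is the classical grand-average ERD and recovers a configured
  magnitude without bias. Parameter-recovery checks use this
  estimator: on a default 15-subject study all six commands are
  recovered within ±5 points at their template peak channels.

## Classification

Schemes: LL–LR, CL–CR, LU–LD (2-class), LL–LR–LU–LD, CL–CR–LU–LD
(4-class), all six (6-class). The participant-level 70/30 holdout
floors the training side (15 subjects → 10 train / 5 test), keeping
subject sets disjoint — an explicit leakage guard asserted in tests.
Cross-validation is stratified 10-fold at *trial* level within the
training partition only; this matches common practice but is optimism-
prone relative to subject-level folds, so a future leave-one-subject-
out evaluation remains the stricter protocol.

Families, all at conventional defaults: pooled-covariance LDA
(automatic lsqr+shrinkage fallback with a logged warning when the
pooled covariance conditioning exceeds 1e10); linear SVM, C = 1,
one-vs-one; Gaussian naive Bayes; and a shallow ANN — one hidden layer
of 10 tanh units, softmax/cross-entropy output, Møller's scaled
conjugate gradient full-batch optimizer, Nguyen–Widrow initialization,
≤ 1000 epochs, minimum gradient 1e-7, early stopping after 6
consecutive validation failures on a seeded stratified 15 % split of
the training partition (the patience rule fixes the count, not the
split size; 15 % is this package's choice). The network and optimizer
are implemented in `ann.py` (no installed library offers this training
regime) and verified against numerical gradients. Features are
z-scored by training statistics for the scale-sensitive families (SVM,
ANN); LDA and NB consume raw ERD %. Prediction ties resolve to the
fixed command order LL, LR, CL, CR, LU, LD.

## Evaluation

Per-command accuracy is per-class recall from the confusion matrix
(the most natural reading of per-command reporting; precision or
one-vs-rest accuracy would differ on unbalanced predictions). The
Wolpaw ITR uses one 5 s imagery phase per selection (12/min) by
default; published ITR figures are notoriously sensitive to the
assumed trial time, so reports always state the T used and T is
configurable. Paired scheme comparisons are two-sided paired t tests
with Cohen's d = mean difference / SD of paired differences and a
t-based 95 % CI; the pipeline pairs per-test-subject × per-family
accuracies across schemes (a defensible unit when the evaluation
split is fixed), reports them uncorrected, and adds a clearly-labelled
Holm-adjusted column as an extension. Zero-variance difference
sequences are flagged rather than erroring (d = 0 for identical
sequences, signed infinity for a constant shift, p undefined).

## Numerical and degenerate-input choices

* Band edges inclusive on the 1 Hz grid; empty bands error.
* Zero baseline band power errors naming the channel (a dead channel
  would otherwise produce ±inf ERD); `validate_recording` flags
  constant channels, unordered or out-of-range events without raising.
* ITR below chance is an error at the formula level; evaluation
  reports clamp it to 0 bits/min so degenerate cells stay reportable.
* EDF files are written by a minimal 16-bit standard-EDF writer (one
  data record, per-channel physical scaling; quantization error
  ≤ range/65535) and read back through `mne`, an independent
  implementation; CSV recordings carry events and sampling-rate
  metadata in plain-text sidecars.
* Determinism: identical config + seed reproduce signal matrices,
  feature tables and summary CSVs byte-for-byte (asserted in tests).

## Problem sizes used in the test and acceptance runs

Unit and property tests use 2–8-subject studies (tens of seconds
total). The acceptance suite and `scripts/acceptance.py` run the full
default design — 15 subjects, 2160 trials — once for the effect-bearing
study and once for a null (zero-ERD) study, streaming subject-by-
subject so peak memory stays near 60 MB; a full acceptance run takes
about two minutes on one CPU.

## Known limitations

* Synthetic data only validates the chain's calibration; absolute
  accuracies on it do not transfer to human EEG (our subject-held-out
  accuracies land below within-subject figures typical of real
  studies, as expected for cross-subject transfer with untuned
  templates).
* Trial-level CV inside training subjects is optimistic relative to
  subject-level folds.
* The ratio-statistic bias of per-trial ERD means (documented above)
  is inherent to the feature definition; classifiers are unaffected
  (the bias is monotone per channel) but feature-level means should be
  read with it in mind.
* No artifact model: the notch/bandpass chain is exercised against
  line noise and drift only.
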