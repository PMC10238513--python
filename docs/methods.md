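# Methods

## Problem and model

`auscult` classifies pediatric digital lung auscultation (DLA) recordings into
four diagnostic categories — control, pneumonia, wheezing disorder,
bronchiolitis — at the *patient* level. A patient contributes up to eight
mono 4 kHz recordings, one per thoracic quadrant (4 anterior + 4 posterior,
fixed canonical ordering). The pipeline has three stages:

1. **Audio classifier.** Each recording is converted to a band-limited
   log-mel spectrogram (Hann window 256 samples / 64 ms, hop 64 samples /
   16 ms, hence 62.5 frames/s; magnitudes between 250 and 750 Hz projected
   onto 32 mel bands, HTK mel scale, log with a 1e-10 floor). A 5-second
   training crop therefore yields a 32 x 313 matrix. A CNN of five
   convolutional blocks (two 3x3 convolutions + batch norm + ReLU each;
   channels 64-128-256-512-1024; 2x2 average pooling after the first four
   blocks; dropout 0.2 after each downsampling) reduces the input to a
   sequence of T feature vectors of width 1024, one per *segment* (16 STFT
   frames of stride after four time poolings). Two per-segment heads emit a
   prediction p(x_i) (sigmoid) and an attention logit v(x_i) (tanh); the
   softmax-normalized attention g(x_i) pools the segment predictions into a
   clip score p(x) = sum_i g(x_i) p(x_i), a convex combination of the
   p(x_i). At inference the network consumes recordings of any duration;
   fixed-size crops are purely a training-time batching device.

2. **Site aggregation.** The eight clip scores of a patient (canonical site
   order; patients missing a site are excluded here) form a length-8 vector
   scored by an L2-regularized logistic regression fitted on the train+tune
   folds. For the four-class diagnosis, the four binary models' 4x8 score
   array is column-L1-normalized, flattened class-major to 32 features, and
   classified by a multinomial logistic regression.

3. **Interpretation (MAD).** For an annotated recording, each segment is
   assigned to the respiration phase covering the majority of its
   receptive-field time span. With alpha_in / alpha_out the mean attention
   over inspiration / expiration segments, the Mean-Attention Difference is
   MAD = (alpha_out - alpha_in) / max(alpha_out, alpha_in), in [-1, 1];
   positive values mean the model listens more to expiration. MAD is
   scale-free in g and exactly antisymmetric under phase-label swap. The
   case alpha_in = alpha_out = 0 cannot occur because softmax attention is
   strictly positive.

## Training recipe

One binary model per class (one-vs-rest), BCE loss on the clip-level
prediction with the patient diagnosis broadcast to all of the patient's
recordings (no per-clip labels exist). AdamW (weight decay 0.005) with a
1cycle schedule peaking at 1e-3 (cosine phases, initial = max/25, final =
initial/1e4, 30% warm-up), batch size 64. Sampling is balanced so that in
expectation half the draws are the target class and each other class gets
one sixth, with recording centres equiprobable within a class; an epoch is
exactly N draws with replacement (N = number of training recordings),
ceil(N/64) steps. The standard recipe runs 100 epochs and evaluates the tune
fold from epoch 60 on (every epoch) with the *mean positional AUROC* — one
AUROC per thoracic site over recording scores, averaged — keeping the best
checkpoint. Sites with single-class tune labels are dropped from the mean
with a warning.

## Evaluation protocol

Nested stratified 5-fold cross-validation on patients: every ordered
(test fold, tune fold) pair is one split, so k = 5 gives 20 splits; all
recordings of a patient stay in one fold. Sensitivity and specificity are
computed at a fixed 0.5 threshold on the aggregator probability (the
operating point is configurable; no a-priori trade-off is imposed) with
exact Clopper-Pearson 95% intervals; AUROC is the rank statistic with ties
half-credited and carries a DeLong 95% interval (variance from placement
values; a zero-variance interval is returned degenerate with a warning).
Ensemble (external-style) prediction averages the per-split models' patient
probabilities. A clinical baseline fits a logistic regression on
standardized (age, respiratory rate), grid-searching C in {0.01, 0.1, 1,
10, 100} and penalty in {L1, L2} on the train fold scored by tune AUROC,
then refitting on train+tune. The inference sweep crops recordings from the
start to 2.5-30 s (2.5 s steps) over nested position subsets anchored on
the anterior superior sites ({1, 2, 4, 8} positions; the 4-set adds the
posterior superior pair), refits an aggregator of matching dimensionality
per cell, and reports test AUROC; the 30 s / 8-position cell reproduces the
standard pipeline exactly.

## Numerical implementation

The network, its backpropagation, AdamW and the 1cycle schedule are
implemented directly on NumPy arrays (float32). Gradient correctness is
pinned by per-layer and end-to-end finite-difference tests; a float64 clone
of the stack agrees with finite differences to ~1e-5 relative at
eps = 1e-7, so the float32 tests use tolerances at the rounding-noise floor
(~2e-3 absolute). Convolutions are evaluated as nine shifted tensor
contractions; 2x2 average pooling uses ceil-mode with edge cells averaged
over available inputs only, so T = ceil(frames / 16) for the full
architecture (313 -> 20). Batch normalization follows the usual
training/inference split (momentum 0.1, eps 1e-5) and is also applied to
the raw log-mel input with the 32 mel bands as channels, normalizing each
frequency band independently. Prediction/attention heads are
zero-initialized: an untrained model outputs exactly p = 0.5 with uniform
attention, making the initial BCE equal ln 2 (a fixture the tests use).
SpecAugment masks (2 frequency masks up to 8 bands, 2 time masks up to 32
frames — chosen as standard practice scaled to the 32x313 input) fill with
the per-band mean, i.e. the band-normalized zero.

**Receptive field.** Layer-composition arithmetic and a gradient-support
probe agree that one segment of the full architecture sees 172 input frames
(the probe is exact for reduced configurations too). The conventional
78-frame / 1296 ms span is nevertheless retained as the *reporting*
geometry of the standard configuration (`ModelConfig.rf_frames = 78`) for
mapping segments to time spans and attention curves; reduced configurations
use their measured width. Segment spans are centred on multiples of the
16-frame stride (256 ms) and clipped to the clip bounds.

**Degenerate inputs.** Clips shorter than one analysis window produce a
single-frame spectrogram; inference inputs are zero-padded so at least one
segment exists; a zero-sum column in the multi-class normalization is left
as zeros rather than inventing uniform evidence; an L1/L2 logistic fit on
constant features reduces to the intercept, predicting class prevalence.

## Synthetic cohorts

Because clinical auscultation audio is rarely shareable, validation runs on
simulated patients whose generative model carries exactly the structure the
pipeline assumes (and is itself tested): breath sounds are 250-600 Hz
Gaussian noise amplitude-modulated by the respiratory cycle (inspiration
drawn U(0.5, 1.0) s, expiration U(0.8, 1.5) s, short pauses; inspiration
slightly louder, gain 1.0 vs 0.92); wheezing disorder adds an expiratory
FM tone (350-650 Hz, +-20 Hz vibrato at 5 Hz, gain 1.6 relative to
unit-RMS breath noise); pneumonia adds damped-noise crackles (5-20 ms,
2-5 per cycle, gain 3) confined to a contiguous 2-3-site lobar subset
during inspiration; bronchiolitis adds a mild biphasic wheeze (gain 0.35)
plus diffuse crackles. Each centre contributes a distinct coloured noise
floor (low-pass rumble vs high-pass hiss, gain 0.25) so that centre
identity is learnable from spectra — the acquisition-bias hazard the
balanced sampler exists to blunt. Age and respiratory rate are drawn
class-conditionally (bronchiolitis patients are infants; all disease
classes have elevated RR; RR missing with probability 0.06). The default
cohort is 120 patients (15 per class per centre, 2 centres), 30 s clips,
seed 1234. Gains were calibrated once against the generator's own
contracts — expiratory 350-650 Hz band-power contrast >= 3 dB for wheeze
patients and within +-1 dB of 0 for controls — and a trivial band-power
energy-ratio classifier separates wheeze from control with AUROC > 0.9, so
the learning task is solvable by construction and downstream failures
indicate pipeline bugs rather than impossible data.

What the simulator does *not* model: thoracic acoustic transfer, heart and
stomach sounds, device filtering, recording-length variation, and real
inter-patient acoustic variability. Passing parameter-recovery tests
therefore demonstrates that the pipeline's machinery works, not that the
clinical performance of any trained model transfers to real patients.

## Desk-scale experiment sizes

The parameter-recovery experiment (`auscult.experiments`) trains a reduced
two-block model (channels 8 and 16, measured 18-frame receptive field) for
10 epochs with selection from epoch 6, on the first nested-CV split of the
default cohort (72 train / 24 tune / 24 test patients; 576 training
recordings, 9 steps per epoch). These sizes are the package's chosen
desk-scale defaults; the full five-block/100-epoch recipe is implemented
and configurable but sized for GPU-class hardware.

## Known limitations

* The NumPy network trains on CPU only; wall-clock cost limits the widths
  and epochs practical for routine testing.
* The multi-class fusion follows the raw positional score array of the four
  binary models (not the binary aggregators' patient probabilities).
* MAD is computed against the model chosen by the caller; by convention the
  healthy-vs-pathological or per-disease model can both be interrogated,
  and the choice is a parameter rather than a fixed rule.
* Vertical averaging of cross-validated ROC curves is provided for plotting
  only and has no inferential interpretation.
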