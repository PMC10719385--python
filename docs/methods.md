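# Methods

`mmgdecode` implements an envelope-based decoding analysis for simultaneous
surface electromyography (EMG) and optically-pumped-magnetometer
magnetomyography (OPM-MMG) recordings of finger flexor muscles. The analysis
asks whether 100 ms snippets of the muscle signal suffice to tell an index
finger (DII) flexion from a little finger (DV) flexion from rest, how the two
sensor modalities compare, and which channels carry the discriminative
signal.

## Pipeline

1. **Preprocessing.** Each session is demeaned per channel, band-pass
   filtered 25–100 Hz and band-stop filtered 49–51 Hz with zero-phase
   (forward–backward) fourth-order Butterworth IIR filters, reduced to its
   instantaneous amplitude (magnitude of the analytic signal from the
   Hilbert transform), and resampled to 200 Hz.
2. **Window sampling.** Trials — not windows — are split by stratified
   5-fold cross-validation. Within a fold, 500 training and 100 test windows
   of 100 ms (20 samples × C channels) are sampled per class, with
   replacement, uniformly over all admissible (trial, offset) pairs:
   movement windows 0–300 ms after onset from that class's trials,
   no-movement windows from the pre-onset rest (−1500–0 ms), half from DII
   and half from DV trials. Every window lies inside one trial, so train and
   test windows never share autocorrelated signal. Windows are z-scored per
   feature (time × channel) with moments fitted on the training split only.
3. **Classifier.** A residual 1-D convolutional network: a residual block
   (pointwise convolution with 128 filters → batch-norm → GELU →
   kernel-3 convolution back to C filters → batch-norm → GELU → add the
   block input → GELU), a kernel-3/stride-2 convolution with 16 filters and
   GELU, then flatten → dropout 0.1 → FC(100)+GELU → dropout →
   FC(100)+GELU → dropout → FC(3)+softmax. Training uses categorical
   cross-entropy, Adam (learning rate 0.01, β₁ = 0.9, β₂ = 0.999), batch
   size 250, shuffling each epoch, no early stopping and no validation
   split. One network per fold and modality is trained from scratch.
4. **Attribution.** Integrated gradients of the per-sample loss at the true
   label, with an all-zero baseline and m = 6 interpolation levels linearly
   spaced on [0, 1] (endpoints included; plain average of the gradients).
   Per-sample T × C attribution maps are L1-normalized, averaged over time,
   then over test samples, giving one score per channel and fold. Both the
   signed mean and the mean of absolute per-sample channel scores are
   reported; ranking analyses use the absolute variant because the sign of
   a loss gradient is not comparable across channels.
5. **Statistics.** The empirical chance level permutes the training labels
   and reruns the full cross-validation (`n_perm` times); p is the fraction
   of null values exceeding the observation (reported as "< 1/n_perm" when
   none does; an add-one estimator is available), and Cohen's d is the
   observation minus the null mean over the null's sample standard
   deviation. The two modalities are compared with the combined 5×2-CV
   F-test, f = (Σ d²ᵢⱼ)/(2 Σ s²ᵢ) on F(10, 5), over five replications of a
   fresh stratified 50/50 trial split, and with the continuity-corrected
   McNemar test χ² = (|b−c|−1)²/(b+c) on the discordant counts, with
   Cohen's g = |b/(b+c) − ½|. Agreement between the modality models'
   predictions on identical test windows is summarized by the consensus
   matrix, percentage agreement, and Cohen's kappa.

## Synthetic data generator

Real paired OPM-MMG/EMG recordings of this protocol are not publicly
deposited, so the package ships a generator that emulates the experiment's
statistical structure with known ground truth: three sessions of 30 cued
trials (all-DII, all-DV, alternating), one cue every 5 s, movement onset
0.3 s after the cue, 5 s trials at 2343.8 Hz, 4 bipolar EMG channels and 8
OPM channels (4 biaxial sensors, Y and Z axes).

Each movement is a burst of 25–100 Hz band-limited Gaussian noise lasting
1 s, shaped by a tapered-cosine (Tukey) envelope with 100 ms raised-cosine
attack and release ramps around a flat sustain. The fast attack matters: a
symmetric Hann envelope over the full movement would leave the 0–300 ms
post-onset interval — the interval the analysis samples its movement
windows from — almost without burst energy, making a large share of
movement windows undecodable at any SNR, which contradicts both real
flexion electromyograms (rise times of order 100 ms) and the decoding
performance observed on the real recordings. The ramp length is
configurable (`burst_ramp`; `move_len/2` recovers the Hann).

Bursts are scaled per channel by a class-dependent gain matrix: radial-side
channels (sensors 1, 3) respond preferentially to DII, ulnar-side channels
(sensors 2, 4) to DV, and OPM Z-axis (skin-perpendicular) channels are
weighted above Y-axis ones — the spatial structure the real recordings
showed. The background is 1/f Gaussian noise (unit RMS), a 50 Hz line
component (amplitude 0.5, random phase per channel), and white sensor noise
(RMS 0.3). SNR is defined per modality as burst RMS (at gain 1, after the
taper) over the background RMS in the 25–100 Hz band of the same channel.

Default SNRs are `snr_emg = 1.5` and `snr_mmg = 0.9`. They were calibrated
so that the full pipeline operates in the accuracy regime reported for the
real single-participant recordings (EMG ≈ 95%, MMG ≈ 89%): at the 100-epoch
5-fold protocol the defaults give ≈ 0.97 (EMG) and ≈ 0.89 (MMG) mean CV
accuracy. Only these ratios matter downstream — units are arbitrary because
every window is z-scored.

What the generator does **not** emulate: volume conduction and magnetic
forward fields (bursts are independent across channels, so cross-channel
correlations of real recordings are absent), motor-unit action potential
structure, movement artifacts, sensor drift, heartbeat interference, and
reaction-time jitter (the cue-to-onset latency is a fixed 0.3 s). Passing
tests therefore show that the pipeline recovers the structure the generator
puts in — class-dependent spatial amplitude patterns at realistic SNR — not
that it handles every nuisance of real data.

## Numerical choices

- **Filters.** "Fourth order" is the design order of the one-way filter;
  the forward–backward pass squares the magnitude response. Reflect
  padding, with the pad length chosen so the filter transient decays below
  1e-9 (the 2 Hz notch has poles near the unit circle and needs ≈ 8 s of
  padding at 2343.8 Hz; shorter signals raise an error). This makes
  zero-phase filtering symmetric under time reversal to ~1e-8.
- **Resampling** is FFT-based with output length `round(n·fs_out/fs_in)`
  (2343.8 Hz has no small rational ratio to 200 Hz); the envelope is
  clipped at zero afterwards because FFT ringing can dip marginally below.
- **Network numerics.** The network is implemented directly in NumPy
  (forward, backward, Adam); it is small enough that this trains in ~20 s
  per fold on one CPU core and is bit-reproducible from one integer seed.
  Batch-norm normalizes per filter over batch × time (momentum 0.99,
  eps 1e-3, running moments at inference); weights use fan-in-scaled
  Gaussian initialization; the stride-2 "same" convolution pads the extra
  sample on the right (output length ⌈T/2⌉ = 10, flatten size 160).
  Arithmetic runs in float32 by default (configurable); the backward pass
  is verified against finite differences in float64.
- **Z-scoring** uses the sample (n−1) standard deviation; a constant
  feature in the training windows raises an error naming the feature.
- **Seeds.** All child seeds derive from one master seed by fixed integer
  arithmetic (a multiply-fold kept below 2³¹), so every stage — generation,
  fold split, window sampling, weight initialization, shuffling, dropout,
  permutations — is reproducible from a single integer.
- **Degenerate statistics** raise explicit errors rather than returning
  NaN: zero 5×2 variance (identical models), no discordant McNemar pairs,
  chance agreement of 1, zero-variance permutation null.

## Scaled protocols

The full analysis driver defaults to 100 training epochs (training loss
plateaus well before that, consistent with the loss curves the package
plots) and runs the permutation chance level at a reduced size —
n_perm = 100 with 60/30 windows per class and 3 epochs — since a
label-permuted pipeline sits at chance regardless of training effort; the
5×2-CV F-test replications in the acceptance script use 50 epochs. All of
these are configuration values (`RunConfig`), not limits of the
implementation; the original study-scale protocol (250 epochs,
n_perm = 1000) is a configuration change.

## Known limitations

- The permutation p-value resolution is 1/n_perm; at the scaled default
  (100 permutations) the smallest reportable value is "< 0.01".
- The 95% confidence intervals that can be quoted alongside Cohen's d for
  this kind of analysis are not computed (no method is specified for them
  that this package could faithfully reproduce).
- Real-data ingest accepts the package's HDF5 + events-TSV contract only;
  proprietary acquisition-system formats must be converted externally.
- With near-ceiling accuracies the McNemar discordant counts b + c can be
  small; the test then has little power and its χ² is dominated by the
  continuity correction.
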