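# Methods

This note documents the models and procedures implemented in `usvkit`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic test world does and does not
establish.

## Spectrogram as image

Recordings are mono PCM WAV, nominally 250 kHz; loading rejects stereo
files and sampling rates below twice the 110 kHz analysis ceiling. The STFT
uses a 256-sample Hamming window, hop 128 (half overlap) and a 1024-point
FFT: at 250 kHz this gives 244.14 Hz bins and 0.512 ms frames, and the
frame count is exactly `floor((n - 256)/128) + 1` (no edge padding). Power
is `10 log10 |X|^2` with the linear power floored near machine-tiny so
digital silence stays finite. Rows below the 45 kHz high-pass are dropped —
audible-band sound is out of scope by design.

One axis convention is shared by every stage: rows are frequency bins
ascending from the cutoff, columns are time frames, coordinates are
(row, col), and times/frequencies are reported at bin centers.

The gray image is `J = clip((|P_dB|/max|P_dB| - L_in)/(H_in - L_in), 0, 1)^gamma`
with defaults `gamma = 1`, `L_in = 0`, `H_in = 1` (a linear full-range
mapping). Because spectral power is below 1, strong signal has *small*
|dB|: the normalised image carries signal as LOW intensity. That polarity is
recorded on the object (`signal_low`) and respected everywhere: the contrast
filter scores the signal-low image, binarisation works on its complement.
This is the only reading under which the published contrast magnitudes for
calls (~0.64) versus artifacts (~0.92) are attainable.

## Segmentation

Binarisation is local-mean adaptive thresholding: a pixel is foreground
when its signal-low value is at least `t = 0.2` below the mean of an
`s x s` neighbourhood, i.e. `dark <= (1 - t) * C`. Local means come from an
integral image (summed-area table) with windows truncated at borders and
divided by the true pixel count, so edges are unbiased. `s` is not fixed by
the method's description; the default is the smallest odd integer at least
1/8 of the smaller image dimension, which is stable across image sizes. An
exactly constant image segments nothing.

Morphology, in order: opening with a 4x2 rectangle; dilation with a
length-4 vertical line; removal of 8-connected components under 60 pixels
(about a 2 ms syllable at default resolution — the size is evaluated after
the vertical dilation, per the listed order); dilation with a length-4
horizontal line. 8-connectivity is used throughout because
frequency-modulated traces run diagonally.

Components whose time gap is under 10 ms merge transitively into one
candidate (sorted sweep; the closure is independent of blob order). Each
candidate is summarised every 0.5 ms by the mean frequency, mean dB
intensity and frequency spread of its member pixels; bins with no pixels
are linearly interpolated and marked unobserved. The unobserved flags
matter: note segmentation inside the classifier looks for >= 6 kHz jumps
between consecutive *observed* points no more than 10 ms apart, so a step
across a short silent gap reads as a discontinuity rather than the ramp the
interpolation drew through it.

### Harmonics

A harmonic is an extra feature of a call, never a separate call. The main
component is the longest one, with durations within 2 ms treated as tied
and resolved by higher mean intensity — a 2x overtone's doubled FM
excursion can smear across marginally more frames than its fundamental, but
it is always weaker. Overtone components must overlap the main component in
time, be continuous, sit near its octave (mean-frequency ratio 1.7-2.4) and
be at least 3 dB weaker. The intensity and octave requirements exist
because fragmented broadband bursts otherwise get their co-temporal
fragments "stripped" as harmonics, leaving a clean tonal track that
masquerades as a call. When a harmonic is found, the main track is
recomputed without its pixels (a bin averaging the fundamental with its
octave would report a frequency between the two) and the overtone gets its
own track.

Candidate images for the trainable classifier are 220 ms windows (twice the
longest USV) centred on the candidate midpoint, full retained frequency
range, resampled to 227x227 and normalised to [0, 1] with signal bright;
edge windows are padded at the background median.

## Local Median Filter

Candidate k's contrast is `C_k = X_hat / W_hat`: the median signal-low
intensity of its pixels over the median of a bounding window extending its
frequency extent by 2.5 kHz and its time extent by 100 ms each way, clipped
to the image. The window median includes the candidate's own pixels (they
are a small fraction of the window). When harmonics were detected, `X_hat`
is taken over the main trace only — overtones are ~10 dB weaker features
and drag the median toward the background.

The per-file threshold comes from the empirical CDF of the `C_k`,
downsampled to 35 points equally spaced along the value axis (cumulative
fractions linearly interpolated). Both axes are normalised to [0, 1] — this
makes the threshold scale-consistent — and curvature is evaluated at every
interior point from a local second-order parametric fit (central
differences; `kappa = (x'y'' - x''y') / (x'^2 + y'^2)^{3/2}`, the standard
plane-curve formula).

The threshold is the strongest concave-up interior curvature extremum whose
CDF height lies in [0.5, 0.9] and after which at least 10% of the mass
arrives within 10% of the value range. Each clause carries method
semantics:

* *concave-up, upper half*: the knee is the foot of the low-contrast
  artifact mass, the point where the CDF bends upward into the artifact
  rise after covering the genuine-call majority. On real validation data
  the published numbers place the threshold (~0.88) at the foot of the
  artifact mode (0.92), not at the end of the call rise.
* *height in [0.5, 0.9]*: the filter's premise is that calls are the
  majority and artifacts a rejectable minority; a knee keeping less than
  half or rejecting less than a tenth contradicts it.
* *the rise requirement*: curvature alone is maximised next to flat
  plateaus, where a single stray candidate imitates a foot; an artifact
  mass must actually be a mass.

Fewer than 5 scores, an exactly flat CDF, or no valid extremum fall back to
the conservative default `tau = 0.92`. Candidates with `C_k <= tau`
(inclusive) survive. The threshold is strictly per file: it absorbs
differences in microphone gain and distance.

## Classification

The rule-based classifier is a deterministic decision tree over the track,
evaluated in this precedence (note count first, then single-note shape):

1. broadband guard: a track whose median instantaneous bandwidth exceeds
   15 kHz, whose 90th percentile exceeds 20 kHz, or whose estimated
   frequency span exceeds 45 kHz is noise — every defined class is a tonal
   shape, and broadband bursts are none of them;
2. four or more notes: multiple steps; three: two steps; two: step up/down
   by the sign of the observed jump;
3. one note: >= 2 directional changes (sign changes of the smoothed
   derivative with > 6 kHz excursion; 2 ms smoothing window suppresses
   bin-to-bin jitter): complex; exactly one change with the peak (trough)
   >= 6 kHz above (below) both endpoints: chevron (reverse chevron); net
   change >= 6 kHz: up/down frequency modulation; total modulation
   <= 5 kHz: flat if longer than 12 ms, short otherwise; anything left —
   including the deliberately undefined 5-6 kHz modulation band — is noise.

The trainable classifier is a small one-hidden-layer network over
downsampled candidate images (scikit-learn's `MLPClassifier` driven
per-epoch): SGD with momentum 0.9, learning rate 1e-4, weight decay 1e-4,
batch 128, at most 100 epochs, stratified 90/10 train/validation split,
training reshuffled every epoch, early stop after 3 epochs without
validation improvement, fully seeded. Those optimiser defaults follow the
published recipe for the original transfer-learning CNN; the network itself
is deliberately small because no deep-learning stack is assumed — desk-scale
tests use a larger learning rate, which the config exposes. The USV
decision compares the summed probability of the 11 vocal classes with the
noise probability; candidates where neither side reaches 0.7 are flagged
low-confidence for manual review.

## Detection metrics

Detections match annotations one-to-one by onset within +-5 ms, greedy by
ascending |dt| with ties to the earlier annotation (deterministic and
order-independent). Matched call annotations are true positives when the
pipeline called them calls and false negatives when it called them noise;
unmatched call annotations are false negatives; detections matching no call
annotation are true negatives (pipeline said noise) or false positives
(pipeline said call). Rates are percentages per file; aggregates are mean,
SEM (sample sd / sqrt(n)), median and a Student-t 95% CI — the t-based CI
reproduces the published interval half-widths exactly. Rates with zero
denominators are reported as undefined for that file and excluded from
aggregates with a warning.

## Diffusion maps

`W_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))` on plain Euclidean distances
between 11-dimensional probability rows, `sigma = 0.5` by default (the
scale of intra-class distances). `M = D^{-1} W` is row-stochastic; its
spectrum comes from the symmetric conjugate `M_s = D^{1/2} M D^{-1/2}`
(symmetrised to machine precision before `eigh`), with right and left
eigenvectors `Psi = D^{-1/2} Omega`, `Phi = D^{1/2} Omega`. Diffusion time
enters as `Lambda^t` with `t = 2`; coordinates are columns 2-4 of
`Psi Lambda^t` (the first column is constant). Eigenvector signs are fixed
so each vector's largest-magnitude entry is positive, and ties in
eigenvalue order are broken deterministically — embeddings are reproducible
up to per-coordinate sign under row permutation.

Repertoire structure is the matrix of Euclidean distances between per-class
centroid coordinates; repertoires are compared by Pearson correlation over
the strict upper triangle.

## Manifold alignment

Within-domain graphs are Gaussian-weighted k-NN graphs (k = 10, symmetrised
by max) with `L = D - W`; the cross-domain similarity Laplacian `Ls` links
every same-label pair with unit weight, the dissimilarity Laplacian `Ld`
every different-label pair (binary weights; the source method leaves the
edge weighting open). The joint map solves
`Z (L + mu Ls) Z^T V = lambda Z Ld Z^T V` with `Z = diag(X1, X2)` and
`mu = 1`, taking eigenvectors of the smallest nonzero eigenvalues (relative
floor 1e-8); a singular right-hand side is ridge-regularised by
`1e-9 * trace`. Domain i projects as `v_i^T X_i`.

Alignment quality: a linear discriminant is trained on the first domain's
projected samples and predicts the second domain's labels — with balanced
domains this is "trained on half of the samples to predict the other half",
and it measures *transfer*: a misaligned joint space scores at chance even
though each domain is internally separable, which a pooled random split
cannot detect (half of its test set always carries clean within-domain
structure). A pooled stratified split remains available (`split="half"`).
The discriminant sees the leading half of the extracted features: on a
self-copy the smallest-eigenvalue eigenvectors are exactly block-symmetric
(copy pairs coincide to machine precision) while the trailing eigenvectors
are antisymmetric single-domain directions that do not transfer and only
let the discriminant overfit.

The confusion matrix yields overall accuracy, Cohen's kappa
`(p0 - pe)/(1 - pe)`, its large-sample variance via the standard
theta-expansion (theta1 equals overall accuracy — asserted in tests), the
Z-score and the 95% CI `kappa +- 1.96 sqrt(var)`.

## The synthetic world

The generator states one world and the tests live in it:

* noise floor -60 dBFS; calls default to -35 dBFS (~25 dB SNR) with a
  +-3 dB per-call spread; 1 ms cosine amplitude ramps;
* all trajectories stay in 47-110 kHz — the 45 kHz high pass would crop
  class-defining geometry out of the image, which is a property of the
  *pipeline*, not a free choice of the generator;
* step-class templates separate their notes by 2-8 ms silent gaps (steps
  are defined for gaps up to 10 ms); all class geometry keeps >= 1 kHz
  margin from every decision threshold, and the 5-6 kHz modulation band is
  never generated — it is deliberately undefined;
* harmonics render at twice the frequency, 10 dB down, only on templates
  whose octave fits below Nyquist without pushing the fundamental under
  47 kHz (flat and short calls in the benchmark session);
* broadband bursts are loud (-32 dBFS, 5-20 ms, 30-120 kHz): they have
  genuine contrast, survive the Local Median Filter as real external noise
  does, and must be rejected by classification;
* clutter blips are faint short tones (-56 dBFS, 5-7 ms) that segment
  marginally and score `C_k ~ 0.78-0.81`: they emulate the low-intensity
  population that dominates real candidate pools (~43% of candidates on
  real validation data, at contrast ~0.92) and that the Local Median
  Filter exists to reject. Without this mass the contrast CDF of a clean
  synthetic session is unimodal and the inflection threshold has no knee
  to find — the benchmark session therefore includes it, and clutter is
  not listed in the ground-truth table, exactly as real segmentation
  artifacts are not annotated events;
* calls are spaced >= 15 ms apart so the 10 ms merge rule cannot fuse
  distinct calls; everything is seed-deterministic to the bit.

What a green end-to-end test establishes: the geometry of the whole chain —
onsets within +-5 ms, class recovery, artifact rejection, burst rejection —
under stated, favourable acoustics. What it does not establish: performance
under reverberation, overlapping callers, real microphone/room transfer
functions, or the published accuracy figures on real recordings, which
require the original audio.

## Known limitations

* An instantaneous (gapless) frequency step is smeared by the analysis
  window across ~2 track bins; the jump detector sees two sub-threshold
  diffs and can miss the note boundary. Gapped steps — the common case —
  are unaffected.
* Clutter contrast tops out near 0.81 in this world (tonal events stop
  segmenting before they get any fainter), below the ~0.92 of real
  artifacts; the knee mechanism is exercised, the exact value is not.
* Harmonic detection assumes the octave; higher-order overtones or
  subharmonics are not flagged.
* The trainable classifier is a perceptron head, not the original
  transfer-learning CNN; it demonstrates the training recipe and the
  posterior interface at desk scale and is not expected to reach the
  published 95% validation accuracy on real images.
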