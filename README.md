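# usvkit

Detection, classification and repertoire analysis of mouse ultrasonic
vocalizations (USVs) by image processing of spectrograms.

Mice vocalize between roughly 30 and 110 kHz. `usvkit` treats a 250 kHz
recording's spectrogram as a gray-scale picture and finds syllables the way a
document binariser finds ink: adaptive thresholding against a local mean,
morphological clean-up, connected components merged by the minimum
inter-syllable interval (10 ms). Detected candidates are cleaned by a
contrast filter whose per-file threshold is found automatically from the
curvature of the contrast distribution, classified into 11 standard syllable
shape classes (plus noise), scored against manual annotations, and analysed
at the repertoire level with diffusion maps and manifold alignment.

The package is a library: the importable API is the interface, and
`examples/` holds one short narrative script per capability.

## The method in brief

**Detection.** The short-time Fourier transform (1024-point FFT, 256-sample
Hamming window, half overlap) gives a dB power image `P(t, f)`; rows below
45 kHz are dropped; intensities are normalised as `J = |P_dB| / max|P_dB|`
(optionally gamma-corrected). A pixel is foreground when it beats its local
`s x s` mean `C(x, y)` by the sensitivity margin `t = 0.2`, computed in
O(1) per pixel with an integral image. Morphology (4x2 opening, directional
dilations, removal of components under 60 px) yields blobs; blobs closer
than 10 ms in time merge into one syllable candidate, summarised by mean
frequency and intensity every 0.5 ms, with harmonic overtones detected and
kept as features of the call.

**Local Median Filter.** Every candidate k gets a contrast ratio
`C_k = median(candidate pixels) / median(bounding window)`; real calls score
well below 1, segmentation artifacts near 1. The empirical CDF of the
`C_k`, downsampled to 35 points, has an inflection at the foot of the
artifact mass; the maximum-curvature point there is the per-file rejection
threshold `tau` (fallback `tau = 0.92` when no knee exists). Candidates
with `C_k <= tau` survive.

**Classification.** A deterministic rule-based classifier applies the
field's shape definitions over the 0.5 ms track: inter-note jumps >= 6 kHz
within 10 ms define step syllables; modulation <= 5 kHz split at 12 ms
duration defines flat vs short; chevrons need a peak (or trough) >= 6 kHz
from both endpoints; two or more directional changes > 6 kHz make a complex
call; broadband tracks are noise. An optional trainable image classifier
(SGD with momentum, batch 128, 90/10 split reshuffled per epoch, 3-epoch
patience) produces class posteriors, and a candidate counts as a call when
its summed vocal probability exceeds its noise probability.

**Repertoire analysis.** Each syllable's 11-class probability vector is a
point in probability space. Diffusion maps (Gaussian kernel, sigma = 0.5;
row-normalised Markov matrix; spectral decomposition through the symmetric
conjugate; diffusion time t = 2) embed a repertoire in three coordinates.
Repertoires are summarised by pairwise distances between class centroids and
compared via Pearson correlation of those matrices, or aligned into a joint
space by the graph-Laplacian eigenproblem
`Z (L + mu Ls) Z^T V = lambda Z Ld Z^T V`, with alignment quality scored by
overall accuracy and Cohen's kappa (asymptotic variance, Z-score, 95% CI).

## A worked example

```bash
python examples/detect_usvs.py
```

builds a 10 s synthetic session (eight known syllables, two noise bursts,
ten faint clutter blips) and runs the full chain:

```
20 candidates segmented; contrast threshold tau = 0.784 (fallback used: False)
10 candidates kept by the Local Median Filter

 start_s  duration_ms     label  contrast_ck  harmonic  is_usv
0.299520       45.568      flat     0.572781      True    True
1.444352        6.144     short     0.708243     False    True
2.549248       26.112     up_fm     0.671467     False    True
3.674624       42.496   down_fm     0.597828     False    True
4.048384        6.656     noise     0.682387     False   False
4.815872       38.912   chevron     0.643603     False    True
5.953536       50.688   step_up     0.586960     False    True
7.103488       41.472 two_steps     0.624018     False    True
8.243712       59.904   complex     0.667466     False    True
9.202688       12.800     noise     0.650362     False   False
```

All eight generated calls are recovered within a fraction of a millisecond
of their true onsets and labeled with their generating class; the flat call's
overtone is flagged as a harmonic; the two broadband bursts survive the
contrast filter (they have genuine contrast) but are rejected as noise by
classification; the ten faint clutter blips are removed by the filter.

The other examples follow the same pattern: `score_detection.py`
(performance-report arithmetic), `train_image_classifier.py` (the optional
trainable classifier), `repertoire_embedding.py` (diffusion maps and matrix
correlation) and `align_repertoires.py` (manifold alignment and kappa).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline results from scratch: the detection
performance report from seven benchmark confusion-count rows (mean/SEM/
median/CI aggregates of accuracy, sensitivity, specificity and error rates),
and a seeded 60 s synthetic benchmark session — 50 calls across all 11
classes, 20 broadband bursts, 60 clutter blips — pushed through the full
pipeline and scored against its ground truth (detection rate within +-5 ms,
class-label recovery, bursts surviving as calls).
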