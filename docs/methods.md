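# Methods

This note records the models, parameter choices and known limitations of
`braggveto`, in the spirit of a methods appendix: what each stage assumes,
why the defaults are what they are, and what the synthetic benchmark does
and does not demonstrate about real beam-time data.

## Synthetic frame model

The simulator emulates the qualitative structure of reduced SFX detector
frames, not diffraction physics:

- **Background** — a smooth, radially decaying profile (a broad Gaussian in
  radius plus an optional set of scattering rings), normalised so its frame
  mean equals `background_level`, then passed through per-pixel Poisson
  sampling. Real frames add detector gain structure and read noise; the
  Poisson model captures the shot-noise floor that matters for corner
  detection.
- **Bragg peaks (hits only)** — `n ~ Uniform[peaks_per_hit]` isotropic 2-D
  Gaussian spots with amplitude and width drawn per peak from
  `peak_amplitude` and `peak_sigma`. Centres are rejection-sampled to be at
  least 6 px apart (so ground-truth matching at tolerance 3 px is
  unambiguous) and at least `max(border_margin, 2·peak_sigma_hi)` from the
  frame edge. `border_margin` defaults to 20 px so every simulated peak lies
  inside the region where a keypoint patch (circle radius 3 + half patch 15
  = 18 px) can exist; peaks closer to the edge would be undetectable by
  construction and would only add an uninformative ceiling on recall.
  A frame too small to host the requested peaks raises
  `PeakPlacementError` after a bounded number of attempts.
- **Anomalies** — the artefact classes seen on real detectors are modelled
  phenomenologically: water ring (broad additive ring), ice ring (narrow
  bright ring), loop scatter (anisotropic streak), non-uniform response
  (smooth multiplicative gain field), strong background (4× level), hot
  pixels (saturated, masked invalid) and panel gaps (masked stripe).
- **Determinism** — one RNG stream per dataset, split per frame by counter
  (`SeedSequence([seed, frame_index])`), so a single frame can be
  regenerated without its predecessors; the shuffle uses a separately
  tagged stream. Identical config ⇒ bit-identical output.

**Default photon scale.** `background_level = 3000` photons/pixel with peak
amplitudes 3000–20000. The preprocessing step rescales each frame so that
its 99.9th-percentile intensity maps to 255; the Poisson noise of a miss
frame then has an 8-bit standard deviation of roughly 255/√λ ≈ 5, safely
below the FAST contrast margin t = 20, while peaks remain several hundred
photons above their local surroundings after rescaling. This mirrors real
reduced frames, where the water background is smooth at the detector's
dynamic range and Bragg peaks are locally dominant. At substantially lower
photon counts the rescaled shot noise itself triggers the segment test and
miss frames stop being quiet — that regime is reachable through the config
(and is used in the cross-dataset domain-gap tests) but is not the default
operating point.

## ORB extraction

- **Preprocessing** — invalid (masked) pixels are zeroed; valid intensities
  are clipped at their 99.9th percentile (a single hot pixel must not
  swallow the 8-bit range) and linearly rescaled to [0, 255] with
  round-half-even. Constant frames map to all zeros.
- **FAST** — the count-based segment test: a pixel is a corner iff at least
  9 of its 16 circle pixels ("more than eight") are brighter by > t or
  darker by > t. No contiguous-arc requirement by default; the contiguous
  variant is available via `contiguous_arc=True`. t defaults to 20 on the
  8-bit scale — a common choice that gives stable counts at the default
  simulator operating point. The keypoint score is the qualifying count,
  tie-broken by the summed absolute contrast of the qualifying pixels
  (encoded as `count + contrast/4096` so the tie-break can never outweigh
  the count); non-maximum suppression keeps local maxima in a 5 px window,
  and an optional `max_keypoints` cap keeps top scores with (row, col)
  lexicographic tie-break. No Harris re-ranking is applied: the FAST count
  is the only corner response used.
- **Orientation** — intensity-centroid moments over the circular patch of
  diameter 31; θ = atan2(m₀₁, m₁₀), measured from the +col axis toward
  +row, with θ = 0 for zero moments. Under an exact 90° array rotation the
  moments rotate exactly, so θ covariance is exact (note `np.rot90` is a
  *clockwise* rotation in row-down image coordinates, shifting θ by −π/2).
- **rBRIEF** — 256 fixed random pairs: the first point Gaussian about the
  keypoint with spread `patch_size/5`, the second Gaussian about the first
  with twice that spread, both clamped to the patch. The pattern is
  regenerated deterministically from a fixed seed at import, so every
  installation shares the identical pattern without a bundled data file.
  Steered copies are precomputed at the 30 canonical angles (2π/30 = 12°
  bins; bin index = round(θ/step) mod 30) with integer-rounded offsets.
  Bit i = 1 iff the intensity at the first point is *less* than at the
  second — comparisons run on a σ = 2 px Gaussian-smoothed image so
  high-frequency noise does not dominate the bits. Either bit convention
  yields the same Hamming geometry; this one is fixed and documented so
  descriptors are portable.
- **Pyramid** — supported (downsample by 1.2 per level with anti-alias
  smoothing, truncating levels smaller than a patch) but disabled by
  default: on diffraction frames nearly all keypoints appear at full
  resolution, and single-level extraction is markedly faster.

Measured behaviour of the steering table (Monte-Carlo over 100 smooth
random patches, frozen into the tests): descriptors of a patch and its copy
rotated by exactly two bins (24°) differ by at most ~36 of 256 bits, while
unrelated patches sit at the 128-bit chance level. Orientation *estimation*
on weakly oriented patches is noisier than the steering itself; patches
whose centroid offset is a fraction of a pixel can land in a neighbouring
bin. This does not affect hit/miss discrimination, which never compares
descriptors across frames directly.

## Labelling

Hit iff keypoint count ≥ τ (the boundary count = τ is a hit). Calibration
sweeps τ over a grid (default 1–100, covering the range where per-dataset
optima typically land, e.g. 25–40 on real experiments) against reference
labels, computing keypoint counts once; the selected τ* is the smallest
value on the maximum-agreement plateau, which favours sensitivity to weak
hits. The sweep's success rate is overall label agreement; per-class rates
are reported alongside for transparency.

## Bag of visual words

Binary descriptors are relaxed to 0/1 real vectors: squared Euclidean
distance on bit vectors equals Hamming distance, so Euclidean K-means on
the relaxation preserves descriptor geometry while avoiding a bespoke
k-medoids. Sizing is fixed: k = 5·n_classes centres, batch size b = S/3,
K-means++ initialisation on an init_size = 3b subsample, at most 100
iterations with centre-movement tolerance 1e-4, all seeded. Clustering is
delegated to `sklearn.cluster.MiniBatchKMeans` configured with exactly
these rules; the test suite cross-checks it against full-batch K-means run
to convergence with 20 restarts (≥ 95% assignment agreement, inertia
within 5% on separated clouds). Histograms are normalised to frequencies
by default (raw counts behind a flag); descriptor-free frames encode as
all-zero rows rather than being dropped. Frequency normalisation discards
the absolute keypoint count; for tasks where count itself is the signal
(e.g. the five-band quality grading), raw counts are the better encoding
and the multi-class tests use them.

## Classifiers and evaluation

All four models are sklearn estimators with the fixed configurations listed
in the README. Choices the configuration left open:

- SVM penalty C = 1 (sklearn default; the decision boundary on separable
  BoVW features is insensitive to it).
- MLP: constant learning rate 0.01, SGD, max 1000 epochs, stopping when the
  loss improves by less than 1e-6 for 50 consecutive epochs. The 7-layer
  net spends its first ~100 epochs on a flat ln(2)-loss plateau before the
  deep stack starts learning; a looser tolerance (e.g. 1e-4 with patience
  20) stops there and yields a chance-level classifier, so the tight
  tolerance is load-bearing, not cosmetic.
- Gaussian NB variance smoothing 1e-9 of the largest feature variance.
- Multi-class metrics are macro-averaged one-vs-rest; binary metrics treat
  *hit* as the positive class.
- Cross-validation is stratified fivefold (each fold 20% test / 80% train),
  shuffled under the given seed; stratification guards against imbalanced
  folds on small datasets.
- Cross-dataset transfer fits the codebook on the training dataset only and
  encodes the test dataset with it, so the transfer number reflects a true
  deployment scenario.

The full train/evaluate path is deterministic under fixed seeds.

## Benchmark sizes

The standard benchmark is 2000 frames of 256×256 px (1000 hits with 20–100
peaks, 1000 misses, dataset seed 42); it runs end to end — simulation, ORB,
per-fold codebooks, MLP cross-validation — in about a minute on one CPU.
The property suites use 50–120 Monte-Carlo instances each and 60–200-frame
datasets; these sizes give stable pass/fail behaviour at fixed seeds while
keeping the whole suite in the low minutes.

## Limitations

- The simulator's spots are isotropic Gaussians on a smooth background;
  real Bragg peaks have lattice-determined positions, panel seams, and
  correlated backgrounds. Passing the benchmark demonstrates that the
  pipeline's machinery is sound and that its stages compose correctly — it
  does not by itself predict accuracy on any specific real experiment,
  where class overlap (weak hits vs. structured background) is the binding
  difficulty.
- Detection is first-pyramid-level only by design; frames whose peaks are
  many pixels wide (very low-resolution detectors) would need the pyramid
  enabled.
- Descriptor matching across frames (tracking, indexing) is out of scope;
  descriptors exist solely to feed the visual-word histograms.
- Thresholds (τ, FAST t) are dataset-specific by nature; the defaults are
  calibrated to the simulator's operating point and should be re-swept on
  real data against a reference labeller.
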