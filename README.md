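# braggveto

Hit/miss vetoing for serial femtosecond crystallography (SFX) frames.

SFX experiments at X-ray free-electron lasers record diffraction snapshots at
hundreds-to-thousands of frames per second, but only a small fraction are
*hits* — frames where the beam actually struck a microcrystal and produced
Bragg peaks. Everything else is background (water scattering, loop scatter,
detector artefacts) and can be discarded to cut data volume by an order of
magnitude. `braggveto` implements a lightweight, classical-computer-vision
veto for this triage, aimed at crystallographers and beamline data engineers
who want a cheap alternative to full peak finding or CNN classifiers:

1. **ORB keypoints as Bragg-peak proxies** — a from-scratch oriented-FAST /
   rotated-BRIEF extractor. A pixel *p* is a FAST corner if more than eight of
   the 16 pixels on the radius-3 circle around it are brighter than
   *I(p) + t* or darker than *I(p) − t*. Each keypoint gets an
   intensity-centroid orientation θ = atan2(m₀₁, m₁₀) with patch moments
   m₁₀ = Σ x·I(x,y), m₀₁ = Σ y·I(x,y), and a 256-bit steered BRIEF descriptor
   (bit i = 1 iff the intensity at the first point of random pair i is less
   than at the second), steered by a 30-entry lookup table at 2π/30 (12°)
   increments. Detection runs on the first pyramid level only.
2. **Auto-labelling** — a frame is labelled *hit* iff its keypoint count ≥ τ;
   τ is calibrated per dataset by sweeping a grid against reference labels.
3. **Bag of visual words** — descriptors are clustered by mini-batch K-means
   into k = 5·n_classes visual words (batch size b = S/3 for S descriptors,
   init size 3b); each frame becomes a k-bin histogram.
4. **Classification** — configured MLP ({50, 30, 20, 20, 20, 30, 50} hidden
   layers, ReLU, SGD, α = 10⁻⁵), RBF-SVM (γ = 0.001), random forest
   (100 trees, Gini) and Gaussian naive Bayes, evaluated with stratified
   fivefold 80/20 cross-validation (precision, recall, F1, accuracy in %),
   plus cross-dataset transfer matrices and confusion matrices.

A bundled synthetic-frame simulator (radial background + Poisson noise +
Gaussian Bragg spots + optional anomalies such as water/ice rings, loop
scatter, hot pixels and panel gaps) provides labelled data with exact peak
coordinates, so the whole pipeline is testable without beam-time data.

## Worked example

```python
import numpy as np
from braggveto import (SimConfig, generate_dataset, OrbFeatureExtractor,
                       ThresholdLabeler, cross_validate)

frames = generate_dataset(SimConfig(n_hit=100, n_miss=100, seed=3))
labels = np.array([f.truth_label for f in frames])

extractor = OrbFeatureExtractor().fit()       # freezes the BRIEF pattern
descriptors = extractor.transform(frames)     # one (n_i, 32) array per frame

counts = extractor.keypoint_counts(frames)    # cheap per-frame peak proxy
labeler = ThresholdLabeler().fit(counts, labels)
print("calibrated tau:", labeler.tau_)

cv = cross_validate(descriptors, labels, model="mlp", random_state=0)
print(f"MLP 5-fold accuracy: {cv['accuracy_mean']:.2f}% "
      f"+/- {cv['accuracy_std']:.2f}")
```

prints

```
calibrated tau: 2
MLP 5-fold accuracy: 99.50% +/- 1.12
```

i.e. on this 200-frame simulation any keypoint count ≥ 2 already separates
hits from misses perfectly (misses fire essentially no corners at default
signal-to-noise), and the full ORB → bag-of-visual-words → MLP pipeline
classifies held-out frames at ~99.5% mean accuracy across the five folds.

The same stages are available from the shell:

```bash
braggveto simulate --config sim.json --out frames.h5
braggveto extract --in frames.h5 --out feat
braggveto calibrate-tau --in frames.h5 --ref labels.csv --grid 1:100
braggveto label --in frames.h5 --tau 30 --out auto_labels.csv
braggveto run --config pipeline.json          # everything, one output dir
```

## Layout

- `src/braggveto/simulator.py` — synthetic frames with ground-truth peaks
- `src/braggveto/orb.py` — FAST / orientation / rBRIEF, `OrbFeatureExtractor`
- `src/braggveto/labeler.py` — τ-threshold labelling and calibration
- `src/braggveto/bovw.py` — codebook + histogram encoding, `BovwEncoder`
- `src/braggveto/classify.py` — the four classifiers, metrics, CV, transfer
- `src/braggveto/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
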