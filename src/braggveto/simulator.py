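"""Synthetic diffraction-frame simulator with ground-truth Bragg-peak positions.

Serial-crystallography detectors record a smooth scattering background
(water/capillary scattering, falling off with radius) plus, on crystal
"hits", a set of sharp Bragg peaks.  This module generates labelled frames
of that qualitative form — radially modulated background, Poisson counting
noise, isotropic Gaussian spots — together with the exact sub-pixel peak
centres, so the keypoint detector, labeller and classifiers downstream can
be validated without beam-time data.  It deliberately does not model
diffraction physics (no Ewald-sphere geometry, no lattice-dependent spot
positions); anomalies such as water/ice rings, loop scattering, detector
non-uniformity and hot pixels are emulated phenomenologically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

HIT = "hit"
MISS = "miss"

#: Recognised anomaly names, matching classes of artefact seen on real detectors.
ANOMALY_FLAGS = frozenset(
    {
        "water_ring",
        "ice_ring",
        "loop_scatter",
        "nonuniform_response",
        "strong_background",
        "hot_pixels",
        "panel_gaps",
    }
)


class PeakPlacementError(RuntimeError):
    """Raised when peaks cannot be placed at the required separation."""


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one synthetic dataset.

    Parameters
    ----------
    frame_shape : (rows, cols) in pixels.
    n_hit, n_miss : number of frames of each class.
    peaks_per_hit : inclusive [lo, hi] range of Bragg-peak counts per hit.
    peak_amplitude : [lo, hi] peak height in photons above background.
    peak_sigma : [lo, hi] isotropic Gaussian spot width in pixels.
    background_level : mean background in photons/pixel (Poisson mean after
        radial modulation, which is normalised to preserve this frame mean).
    ring_radii : radii (px) of additional scattering rings; empty = none.
    anomaly_flags : subset of :data:`ANOMALY_FLAGS` applied to every frame.
    border_margin : minimum distance (px) of peak centres from the frame
        edge; the effective margin is ``max(border_margin, 2*peak_sigma[1])``.
    seed : RNG seed; identical config (including seed) gives bit-identical
        output.
    """

    frame_shape: tuple[int, int] = (256, 256)
    n_hit: int = 10
    n_miss: int = 10
    peaks_per_hit: tuple[int, int] = (20, 100)
    peak_amplitude: tuple[float, float] = (3000.0, 20000.0)
    peak_sigma: tuple[float, float] = (1.0, 2.0)
    background_level: float = 3000.0
    ring_radii: tuple[float, ...] = ()
    anomaly_flags: frozenset[str] = field(default_factory=frozenset)
    border_margin: float = 20.0
    min_peak_separation: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hit < 0 or self.n_miss < 0:
            raise ValueError("n_hit and n_miss must be non-negative")
        if self.peaks_per_hit[0] < 1:
            raise ValueError("peaks_per_hit.lo must be >= 1")
        for name in ("peaks_per_hit", "peak_amplitude", "peak_sigma"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must satisfy lo <= hi")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        unknown = set(self.anomaly_flags) - ANOMALY_FLAGS
        if unknown:
            raise ValueError(f"unknown anomaly flags: {sorted(unknown)}")
        object.__setattr__(self, "anomaly_flags", frozenset(self.anomaly_flags))
        object.__setattr__(self, "ring_radii", tuple(self.ring_radii))

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class DiffractionFrame:
    """One detector frame plus simulation ground truth.

    ``intensities`` is a non-negative (rows, cols) array in photons.
    ``mask`` is True where the pixel is valid; ``None`` means all valid.
    ``truth_peaks`` holds sub-pixel (row, col) centres — empty for misses.
    """

    intensities: np.ndarray
    mask: np.ndarray | None = None
    truth_peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    truth_label: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        self.truth_peaks = np.asarray(self.truth_peaks, dtype=np.float64).reshape(-1, 2)
        if self.truth_peaks.size:
            r, c = self.truth_peaks[:, 0], self.truth_peaks[:, 1]
            nr, nc = self.intensities.shape
            if np.any(r < 0) or np.any(r > nr - 1) or np.any(c < 0) or np.any(c > nc - 1):
                raise ValueError("truth peaks must lie inside the frame")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensities.shape:
                raise ValueError("mask shape must match intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


def _frame_rng(config: SimConfig, index: int) -> np.random.Generator:
    # One global stream per dataset, split per frame by counter, so any
    # single frame can be regenerated without producing its predecessors.
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(index)]))


def _radial_background(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Expected (noise-free) background, normalised to mean background_level."""
    nr, nc = config.frame_shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    center = np.array([(nr - 1) / 2.0, (nc - 1) / 2.0])
    r = np.hypot(rr - center[0], cc - center[1])
    scale = 0.6 * max(nr, nc)
    profile = 0.35 + np.exp(-((r / scale) ** 2))
    for radius in config.ring_radii:
        profile += 0.5 * np.exp(-0.5 * ((r - radius) / 4.0) ** 2)
    if config.background_level > 0 and profile.mean() > 0:
        profile *= config.background_level / profile.mean()
    return profile


def _place_peaks(
    config: SimConfig, n_peaks: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample peak centres with border margin and pairwise separation."""
    nr, nc = config.frame_shape
    margin = max(config.border_margin, 2.0 * config.peak_sigma[1])
    if nr - 2 * margin <= 0 or nc - 2 * margin <= 0:
        raise PeakPlacementError(
            f"frame {config.frame_shape} too small for border margin {margin}"
        )
    centers: list[np.ndarray] = []
    max_attempts = 200 * n_peaks + 200
    attempts = 0
    while len(centers) < n_peaks:
        if attempts >= max_attempts:
            raise PeakPlacementError(
                f"could not place {n_peaks} peaks at separation "
                f">= {config.min_peak_separation} px in frame {config.frame_shape} "
                f"after {attempts} attempts"
            )
        attempts += 1
        cand = np.array(
            [
                rng.uniform(margin, nr - 1 - margin),
                rng.uniform(margin, nc - 1 - margin),
            ]
        )
        if centers:
            d = np.min(np.hypot(*(np.array(centers) - cand).T))
            if d < config.min_peak_separation:
                continue
        centers.append(cand)
    return np.array(centers).reshape(-1, 2)


def _add_gaussian_spots(
    expected: np.ndarray,
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigmas: np.ndarray,
) -> None:
    """Add isotropic Gaussian spots in place (local 6-sigma stamps)."""
    nr, nc = expected.shape
    for (pr, pc), amp, sig in zip(centers, amplitudes, sigmas):
        half = int(np.ceil(6 * sig))
        r0, r1 = max(0, int(pr) - half), min(nr, int(pr) + half + 1)
        c0, c1 = max(0, int(pc) - half), min(nc, int(pc) + half + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        expected[r0:r1, c0:c1] += amp * np.exp(
            -((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * sig**2)
        )


def _apply_anomalies(
    expected: np.ndarray,
    mask: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Modify the expected image / mask per anomaly flags; returns expected."""
    nr, nc = expected.shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    center = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    r = np.hypot(rr - center[0], cc - center[1])
    flags = config.anomaly_flags
    level = max(config.background_level, 1.0)

    if "water_ring" in flags:
        radius = 0.30 * min(nr, nc)
        expected += 1.5 * level * np.exp(-0.5 * ((r - radius) / 8.0) ** 2)
    if "ice_ring" in flags:
        radius = 0.42 * min(nr, nc)
        expected += 2.0 * level * np.exp(-0.5 * ((r - radius) / 2.0) ** 2)
    if "loop_scatter" in flags:
        # Anisotropic streak from the sample-mounting loop.
        ang = rng.uniform(0, np.pi)
        u = (rr - center[0]) * np.cos(ang) + (cc - center[1]) * np.sin(ang)
        v = -(rr - center[0]) * np.sin(ang) + (cc - center[1]) * np.cos(ang)
        expected += 1.2 * level * np.exp(
            -(u**2) / (2 * (0.4 * nr) ** 2) - (v**2) / (2 * (0.04 * nc) ** 2)
        )
    if "nonuniform_response" in flags:
        gain = 1.0 + 0.3 * np.sin(2 * np.pi * rr / nr) * np.cos(2 * np.pi * cc / nc)
        expected *= gain
    if "strong_background" in flags:
        expected *= 4.0
    if "panel_gaps" in flags:
        gap = max(2, nr // 64)
        row0 = nr // 2 - gap // 2
        mask[row0 : row0 + gap, :] = False
    return expected


def generate_frame(
    config: SimConfig, label: str, rng: np.random.Generator | None = None
) -> DiffractionFrame:
    """Generate one labelled frame.

    A ``hit`` receives ``n ~ Uniform[peaks_per_hit]`` Gaussian spots at
    centres recorded in ``truth_peaks``; a ``miss`` has none.  Hot pixels
    and panel gaps are flagged invalid in the mask.
    """
    if label not in (HIT, MISS):
        raise ValueError(f"label must be '{HIT}' or '{MISS}', got {label!r}")
    if rng is None:
        rng = _frame_rng(config, 0)

    expected = _radial_background(config, rng)
    mask = np.ones(config.frame_shape, dtype=bool)

    if label == HIT:
        lo, hi = config.peaks_per_hit
        n_peaks = int(rng.integers(lo, hi + 1))
        centers = _place_peaks(config, n_peaks, rng)
        amplitudes = rng.uniform(*config.peak_amplitude, size=n_peaks)
        sigmas = rng.uniform(*config.peak_sigma, size=n_peaks)
        _add_gaussian_spots(expected, centers, amplitudes, sigmas)
    else:
        centers = np.empty((0, 2))

    expected = _apply_anomalies(expected, mask, config, rng)
    intensities = rng.poisson(np.clip(expected, 0, None)).astype(np.float64)

    if "hot_pixels" in config.anomaly_flags:
        n_hot = max(1, intensities.size // 20000)
        hr = rng.integers(0, config.frame_shape[0], size=n_hot)
        hc = rng.integers(0, config.frame_shape[1], size=n_hot)
        intensities[hr, hc] = 60000.0
        mask[hr, hc] = False
    intensities[~mask] = 0.0

    return DiffractionFrame(
        intensities=intensities,
        mask=mask if not mask.all() else None,
        truth_peaks=centers,
        truth_label=label,
    )


def generate_dataset(config: SimConfig) -> list[DiffractionFrame]:
    """Generate ``n_hit`` hits and ``n_miss`` misses, deterministically shuffled.

    Frame ``i`` (pre-shuffle order: hits first) draws from an RNG stream
    split off the dataset seed by counter, so datasets are reproducible
    frame-by-frame.
    """
    frames: list[DiffractionFrame] = []
    labels = [HIT] * config.n_hit + [MISS] * config.n_miss
    for i, label in enumerate(labels):
        frames.append(generate_frame(config, label, _frame_rng(config, i)))
    # Shuffle stream is split off by a tag distinct from any frame counter.
    order = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), len(labels), 0x5F])
    ).permutation(len(frames))
    return [frames[i] for i in order]


def match_keypoints_to_peaks(
    keypoints: Sequence | np.ndarray,
    truth_peaks: Sequence | np.ndarray,
    tol: float = 3.0,
) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detected keypoints to true peak centres.

    Pairs are matched in ascending distance order; a pair counts iff its
    Euclidean distance is <= ``tol``.  Returns ``(recall, precision,
    matched_pairs)`` with ``matched_pairs`` as (keypoint_idx, peak_idx).
    Empty truth with empty keypoints gives recall = precision = 1 by
    convention.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    kp = _as_coords(keypoints)
    peaks = np.asarray(truth_peaks, dtype=float).reshape(-1, 2)

    if len(kp) == 0 and len(peaks) == 0:
        return 1.0, 1.0, []
    if len(kp) == 0:
        return 0.0, 1.0, []
    if len(peaks) == 0:
        return 1.0, 0.0, []

    d = cdist(kp, peaks)
    order = np.argsort(d, axis=None, kind="stable")
    used_kp: set[int] = set()
    used_pk: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > tol:
            break
        if i in used_kp or j in used_pk:
            continue
        used_kp.add(int(i))
        used_pk.add(int(j))
        pairs.append((int(i), int(j)))
    recall = len(pairs) / len(peaks)
    precision = len(pairs) / len(kp)
    return recall, precision, pairs


def _as_coords(keypoints) -> np.ndarray:
    """Accept KeyPoint objects, (row, col) tuples or an (n, 2) array."""
    if isinstance(keypoints, np.ndarray):
        return keypoints.reshape(-1, 2).astype(float)
    coords = []
    for kp in keypoints:
        if hasattr(kp, "row"):
            coords.append((float(kp.row), float(kp.col)))
        else:
            r, c = kp[0], kp[1]
            coords.append((float(r), float(c)))
    return np.asarray(coords, dtype=float).reshape(-1, 2)
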