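"""ORB feature extraction for diffraction frames, implemented from scratch.

The extractor follows the classic oriented-FAST / rotated-BRIEF recipe,
restricted by default to the first (full-resolution) pyramid level, which
is where nearly all keypoints on diffraction frames are found:

* **FAST** — a pixel ``p`` is compared with the 16 pixels on a Bresenham
  circle of radius 3 around it; if more than eight of them are brighter
  than ``I(p) + t`` or more than eight are darker than ``I(p) - t``, ``p``
  is a keypoint.  The count-based criterion is used (no contiguous-arc
  requirement); the contiguous variant is available behind
  ``contiguous_arc=True``.
* **Orientation** — the intensity centroid of the circular patch around a
  keypoint defines moments ``m10 = sum(x * I)`` and ``m01 = sum(y * I)``;
  the keypoint orientation is ``theta = atan2(m01, m10)``, measured from
  the +col axis toward +row.
* **rBRIEF** — 256 fixed random pixel pairs inside a 31x31 patch are
  compared on a Gaussian-smoothed image; the pair set is steered by theta
  using a lookup table of 30 precomputed rotations at increments of
  2*pi/30 (12 degrees).  Bit ``i`` is 1 iff the intensity at the first
  point of pair ``i`` is *less* than at the second.

On a Bragg-peak image the bright, sharp spots are exactly the structures
the segment test fires on, so the keypoint count acts as a cheap peak
counter and the descriptors as local peak signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .simulator import DiffractionFrame

#: Bresenham circle of radius 3: 16 (row, col) offsets, clockwise from the top.
CIRCLE_OFFSETS = np.array(
    [
        (-3, 0), (-3, 1), (-2, 2), (-1, 3),
        (0, 3), (1, 3), (2, 2), (3, 1),
        (3, 0), (3, -1), (2, -2), (1, -3),
        (0, -3), (-1, -3), (-2, -2), (-3, -1),
    ],
    dtype=np.intp,
)

N_STEER_BINS = 30  # lookup table granularity: 2*pi/30 = 12 degrees
DEFAULT_PATTERN_SEED = 20111106  # fixed so every installation shares one pattern


class EmptyMaskError(ValueError):
    """Raised when a frame has no valid pixels to preprocess."""


@dataclass(frozen=True)
class OrbConfig:
    """Extraction settings.

    ``fast_threshold`` is the intensity margin ``t`` on the 8-bit scale;
    ``fast_min_count`` is the minimum number of qualifying circle pixels
    (9 = "more than eight").  ``patch_size`` (odd) is the moment/BRIEF
    patch diameter; ``n_bits`` the descriptor length; ``smoothing_sigma``
    the Gaussian width applied before BRIEF sampling.  Pyramid levels
    beyond the first are supported but disabled by default.
    """

    fast_threshold: int = 20
    fast_min_count: int = 9
    circle_radius: int = 3
    patch_size: int = 31
    n_bits: int = 256
    smoothing_sigma: float = 2.0
    n_pyramid_levels: int = 1
    pyramid_scale: float = 1.2
    max_keypoints: int | None = None
    nms_window: int = 5
    contiguous_arc: bool = False

    def __post_init__(self) -> None:
        if not (128 <= self.n_bits <= 512) or self.n_bits % 8:
            raise ValueError("n_bits must be in [128, 512] and divisible by 8")
        if self.patch_size < 7 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 7")
        if not (1 <= self.fast_min_count <= 16):
            raise ValueError("fast_min_count must be in [1, 16]")
        if self.circle_radius != 3:
            raise ValueError("only the 16-pixel radius-3 circle is supported")
        if self.n_pyramid_levels < 1:
            raise ValueError("n_pyramid_levels must be >= 1")
        if self.pyramid_scale <= 1.0:
            raise ValueError("pyramid_scale must be > 1")
        if self.nms_window < 1:
            raise ValueError("nms_window must be >= 1")

    @property
    def border_margin(self) -> int:
        """Minimum keypoint distance from every border (circle + patch)."""
        return self.circle_radius + self.patch_size // 2

    @property
    def n_bytes(self) -> int:
        return self.n_bits // 8


@dataclass
class KeyPoint:
    """A detected corner: integer position, FAST score, orientation."""

    row: int
    col: int
    score: float
    theta: float = 0.0
    level: int = 0


@dataclass
class BriefPattern:
    """The fixed random sampling pattern S plus its 30 steered copies.

    ``points1``/``points2`` are float (n_bits, 2) arrays of (row, col)
    offsets from the keypoint; ``steered1``/``steered2`` are int
    (30, n_bits, 2) rotated-and-rounded versions.  The same pattern is
    used for every keypoint so identical patches give identical
    descriptors.
    """

    points1: np.ndarray
    points2: np.ndarray
    steered1: np.ndarray
    steered2: np.ndarray
    generator_seed: int
    patch_size: int

    @property
    def n_bits(self) -> int:
        return self.points1.shape[0]


def make_brief_pattern(config: OrbConfig, rng_seed: int = DEFAULT_PATTERN_SEED) -> BriefPattern:
    """Draw the BRIEF test pattern and precompute its steered lookup table.

    The first point of each pair is Gaussian about the keypoint with
    spread ``patch_size / 5``; the second is Gaussian about the first with
    twice that spread.  Both are clamped into the patch.  Steered copies
    are generated at the 30 canonical angles ``j * 2*pi/30``.
    """
    rng = np.random.default_rng(rng_seed)
    half = config.patch_size // 2
    sigma = config.patch_size / 5.0
    p1 = np.clip(rng.normal(0.0, sigma, size=(config.n_bits, 2)), -half, half)
    p2 = np.clip(p1 + rng.normal(0.0, 2.0 * sigma, size=(config.n_bits, 2)), -half, half)

    angles = np.arange(N_STEER_BINS) * (2.0 * np.pi / N_STEER_BINS)
    steered1 = np.empty((N_STEER_BINS, config.n_bits, 2), dtype=np.intp)
    steered2 = np.empty_like(steered1)
    for j, a in enumerate(angles):
        steered1[j] = _rotate_offsets(p1, a, half)
        steered2[j] = _rotate_offsets(p2, a, half)
    return BriefPattern(
        points1=p1,
        points2=p2,
        steered1=steered1,
        steered2=steered2,
        generator_seed=int(rng_seed),
        patch_size=config.patch_size,
    )


def _rotate_offsets(points: np.ndarray, angle: float, half: int) -> np.ndarray:
    """Rotate (row, col) offsets by ``angle`` (from +col toward +row)."""
    y, x = points[:, 0], points[:, 1]  # y = row offset, x = col offset
    c, s = np.cos(angle), np.sin(angle)
    xr = c * x - s * y
    yr = s * x + c * y
    out = np.stack([yr, xr], axis=1)
    return np.clip(np.rint(out), -half, half).astype(np.intp)


_PATTERN_CACHE: dict[tuple[int, int, int], BriefPattern] = {}


def default_pattern(config: OrbConfig, rng_seed: int = DEFAULT_PATTERN_SEED) -> BriefPattern:
    """Shared, cached pattern for a given (n_bits, patch_size, seed)."""
    key = (config.n_bits, config.patch_size, int(rng_seed))
    if key not in _PATTERN_CACHE:
        _PATTERN_CACHE[key] = make_brief_pattern(config, rng_seed)
    return _PATTERN_CACHE[key]


# ---------------------------------------------------------------------------
# preprocessing and pyramid
# ---------------------------------------------------------------------------

def preprocess(frame: DiffractionFrame | np.ndarray) -> np.ndarray:
    """Map a frame to 8-bit: mask out invalid pixels, clip hot pixels, rescale.

    Invalid pixels become 0; valid intensities are clipped at their 99.9th
    percentile (so a single hot pixel cannot swallow the dynamic range)
    and linearly rescaled to [0, 255] with round-half-even.  A constant
    frame maps to all zeros.
    """
    if isinstance(frame, DiffractionFrame):
        img = frame.intensities
        mask = frame.mask
    else:
        img = np.asarray(frame, dtype=np.float64)
        mask = None
    if not np.all(np.isfinite(img)):
        raise ValueError("frame intensities must be finite")
    if mask is None:
        valid = np.ones(img.shape, dtype=bool)
    else:
        valid = mask.astype(bool)
        if not valid.any():
            raise EmptyMaskError("frame has no valid pixels")
    vals = img[valid]
    out = np.zeros(img.shape, dtype=np.uint8)
    if vals.max() <= vals.min():  # constant frame
        return out
    clip = float(np.percentile(vals, 99.9))
    if clip <= 0:
        clip = float(vals.max())
    scaled = np.clip(img, 0.0, clip) * (255.0 / clip)
    out[valid] = np.rint(scaled[valid]).astype(np.uint8)
    return out


def build_pyramid(image: np.ndarray, n_levels: int, scale: float = 1.2) -> list[np.ndarray]:
    """Gaussian-smoothed, progressively downsampled image stack.

    Level 0 is the input; level ``i`` has each side ``floor(prev / scale)``.
    Levels that would be smaller than a usable patch are dropped with a
    warning.
    """
    from skimage.transform import resize

    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    levels = [np.asarray(image)]
    for _ in range(1, n_levels):
        prev = levels[-1]
        shape = (int(prev.shape[0] / scale), int(prev.shape[1] / scale))
        if min(shape) < 31:
            warnings.warn(
                f"pyramid truncated at {len(levels)} levels: next level {shape} "
                "is smaller than the patch size",
                stacklevel=2,
            )
            break
        down = resize(prev.astype(np.float64), shape, anti_aliasing=True, mode="reflect")
        levels.append(np.rint(down).astype(prev.dtype) if prev.dtype == np.uint8 else down)
    return levels


# ---------------------------------------------------------------------------
# FAST detection
# ---------------------------------------------------------------------------

def _circle_stack(image: np.ndarray, margin: int) -> tuple[np.ndarray, np.ndarray]:
    """Interior view of the image and its 16 circle-shifted copies.

    Returns ``(center, ring)`` where ``center`` has shape (H', W') and
    ``ring`` has shape (16, H', W'), both int16.
    """
    img = image.astype(np.int16)
    h, w = img.shape
    inner = img[margin : h - margin, margin : w - margin]
    ring = np.empty((16,) + inner.shape, dtype=np.int16)
    for k, (dr, dc) in enumerate(CIRCLE_OFFSETS):
        ring[k] = img[margin + dr : h - margin + dr, margin + dc : w - margin + dc]
    return inner, ring


def _max_contiguous_run(flags: np.ndarray) -> np.ndarray:
    """Longest circular run of True along axis 0 of a (16, ...) array."""
    doubled = np.concatenate([flags, flags], axis=0).astype(np.int8)
    best = np.zeros(flags.shape[1:], dtype=np.int8)
    run = np.zeros(flags.shape[1:], dtype=np.int8)
    for k in range(doubled.shape[0]):
        run = (run + 1) * doubled[k]
        np.maximum(best, run, out=best)
    return np.minimum(best, 16)


def fast_detect(image: np.ndarray, config: OrbConfig) -> list[KeyPoint]:
    """Detect FAST corners with count-based segment test plus NMS.

    A pixel qualifies iff at least ``fast_min_count`` circle pixels are
    brighter than ``I(p) + t`` or at least that many are darker than
    ``I(p) - t``.  The score is the qualifying count, tie-broken by the
    summed absolute contrast of the qualifying pixels; non-maximum
    suppression keeps local score maxima in an ``nms_window`` square.
    Keypoints are returned sorted by (row, col).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    margin = config.border_margin
    if min(image.shape) < 2 * margin + 1:
        return []

    t = int(config.fast_threshold)
    center, ring = _circle_stack(image, margin)
    brighter = ring > (center + t)
    darker = ring < (center - t)
    nb = brighter.sum(axis=0)
    nd = darker.sum(axis=0)

    if config.contiguous_arc:
        count = np.maximum(_max_contiguous_run(brighter), _max_contiguous_run(darker))
    else:
        count = np.maximum(nb, nd)
    is_corner = count >= config.fast_min_count
    if not is_corner.any():
        return []

    # score = count, tie-broken by summed |contrast| of qualifying pixels
    contrast = np.abs(ring - center)
    cb = np.where(brighter, contrast, 0).sum(axis=0)
    cd = np.where(darker, contrast, 0).sum(axis=0)
    side_contrast = np.where(nb >= nd, cb, cd)
    score = np.where(is_corner, count + side_contrast / 4096.0, 0.0)

    if config.nms_window > 1:
        local_max = ndimage.maximum_filter(score, size=config.nms_window, mode="constant")
        keep = is_corner & (score >= local_max)
    else:
        keep = is_corner

    rows, cols = np.nonzero(keep)
    kps = [
        KeyPoint(row=int(r) + margin, col=int(c) + margin, score=float(score[r, c]))
        for r, c in zip(rows, cols)
    ]
    if config.max_keypoints is not None and len(kps) > config.max_keypoints:
        kps.sort(key=lambda k: (-k.score, k.row, k.col))
        kps = kps[: config.max_keypoints]
    kps.sort(key=lambda k: (k.row, k.col))
    return kps


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

_PATCH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _patch_offsets(patch_size: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) offsets of the circular patch of the given diameter."""
    if patch_size not in _PATCH_CACHE:
        half = patch_size // 2
        dr, dc = np.mgrid[-half : half + 1, -half : half + 1]
        inside = dr**2 + dc**2 <= half**2
        _PATCH_CACHE[patch_size] = (dr[inside].astype(np.intp), dc[inside].astype(np.intp))
    return _PATCH_CACHE[patch_size]


def compute_orientation(image: np.ndarray, kp: KeyPoint, config: OrbConfig) -> float:
    """Intensity-centroid orientation of a single keypoint (radians)."""
    return float(
        compute_orientations(image, np.array([[kp.row, kp.col]], dtype=np.intp), config)[0]
    )


def compute_orientations(
    image: np.ndarray, coords: np.ndarray, config: OrbConfig
) -> np.ndarray:
    """Vectorised orientation for an (n, 2) array of keypoint (row, col).

    theta = atan2(m01, m10) with m10 = sum(x I), m01 = sum(y I) over the
    circular patch, x/y measured from the patch centre (x = col, y = row).
    A zero-moment (radially symmetric) patch gives theta = 0.
    """
    if len(coords) == 0:
        return np.empty(0)
    dr, dc = _patch_offsets(config.patch_size)
    img = np.asarray(image, dtype=np.float64)
    rows = coords[:, 0][:, None] + dr[None, :]
    cols = coords[:, 1][:, None] + dc[None, :]
    patch = img[rows, cols]
    m10 = patch @ dc.astype(np.float64)  # x moment
    m01 = patch @ dr.astype(np.float64)  # y moment
    # zero-moment convention, with a tolerance so the float residue of a
    # symmetric patch (|m| ~ 1e-13 * m00) does not produce arbitrary angles
    eps = 1e-9 * patch.sum(axis=1)
    theta = np.arctan2(m01, m10)
    theta[np.hypot(m10, m01) <= eps] = 0.0
    return theta


# ---------------------------------------------------------------------------
# rBRIEF description
# ---------------------------------------------------------------------------

def steer_bin(theta: float | np.ndarray) -> np.ndarray:
    """Index of the 12-degree lookup-table bin containing theta."""
    step = 2.0 * np.pi / N_STEER_BINS
    return (np.rint(np.asarray(theta) / step).astype(int)) % N_STEER_BINS


def rbrief_describe(
    image: np.ndarray, kp: KeyPoint, pattern: BriefPattern, config: OrbConfig
) -> np.ndarray:
    """256-bit steered BRIEF descriptor of one keypoint, packed to bytes.

    ``image`` must already be smoothed (see :func:`smooth_for_brief`); the
    steered pair table whose angle bin contains ``kp.theta`` is used, and
    bit i is 1 iff the intensity at the first point of pair i is less than
    at the second.
    """
    packed = describe_keypoints(
        image,
        np.array([[kp.row, kp.col]], dtype=np.intp),
        np.array([kp.theta]),
        pattern,
    )
    return packed[0]


def describe_keypoints(
    smoothed: np.ndarray,
    coords: np.ndarray,
    thetas: np.ndarray,
    pattern: BriefPattern,
) -> np.ndarray:
    """Vectorised rBRIEF for n keypoints -> (n, n_bits/8) uint8 array."""
    n = len(coords)
    if n == 0:
        return np.empty((0, pattern.n_bits // 8), dtype=np.uint8)
    img = np.asarray(smoothed, dtype=np.float64)
    bins = steer_bin(thetas)
    t1 = pattern.steered1[bins]  # (n, n_bits, 2)
    t2 = pattern.steered2[bins]
    r = coords[:, 0][:, None]
    c = coords[:, 1][:, None]
    v1 = img[r + t1[..., 0], c + t1[..., 1]]
    v2 = img[r + t2[..., 0], c + t2[..., 1]]
    bits = (v1 < v2).astype(np.uint8)
    return np.packbits(bits, axis=1)


def smooth_for_brief(image: np.ndarray, config: OrbConfig) -> np.ndarray:
    """Gaussian smoothing applied before BRIEF sampling (noise robustness)."""
    if config.smoothing_sigma <= 0:
        return np.asarray(image, dtype=np.float64)
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=np.float64), sigma=config.smoothing_sigma
    )


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two packed descriptors."""
    return int(np.unpackbits(np.bitwise_xor(a, b)).sum())


# ---------------------------------------------------------------------------
# end-to-end extraction
# ---------------------------------------------------------------------------

def extract(
    frame: DiffractionFrame | np.ndarray,
    config: OrbConfig | None = None,
    pattern: BriefPattern | None = None,
) -> tuple[list[KeyPoint], np.ndarray]:
    """Full ORB pass on one frame: keypoints plus packed descriptors.

    Runs preprocess -> (pyramid) -> FAST -> orientation -> rBRIEF.  With
    ``n_pyramid_levels > 1`` detection runs per level and positions are
    mapped back to level-0 pixel coordinates; by default only level 0 is
    used.  Keypoints and descriptor rows are index-aligned.
    """
    config = config or OrbConfig()
    pattern = pattern or default_pattern(config)
    img8 = preprocess(frame)
    levels = (
        build_pyramid(img8, config.n_pyramid_levels, config.pyramid_scale)
        if config.n_pyramid_levels > 1
        else [img8]
    )
    all_kps: list[KeyPoint] = []
    all_desc: list[np.ndarray] = []
    for level, img in enumerate(levels):
        kps = fast_detect(img, config)
        if not kps:
            continue
        coords = np.array([[k.row, k.col] for k in kps], dtype=np.intp)
        thetas = compute_orientations(img, coords, config)
        desc = describe_keypoints(smooth_for_brief(img, config), coords, thetas, pattern)
        factor = config.pyramid_scale**level
        for k, th in zip(kps, thetas):
            k.theta = float(th)
            k.level = level
            if level:
                k.row = int(round(k.row * factor))
                k.col = int(round(k.col * factor))
        all_kps.extend(kps)
        all_desc.append(desc)
    descriptors = (
        np.concatenate(all_desc, axis=0)
        if all_desc
        else np.empty((0, config.n_bytes), dtype=np.uint8)
    )
    return all_kps, descriptors


class OrbFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer: frames -> per-frame ORB descriptors.

    ``transform`` maps a sequence of frames (``DiffractionFrame`` or bare
    2-D arrays) to a list of packed uint8 descriptor arrays, one of shape
    ``(n_keypoints_i, n_bits/8)`` per frame.  ``fit`` only freezes the
    BRIEF sampling pattern (``pattern_``); it looks at no data, so the
    same fitted extractor can be reused across datasets.
    """

    def __init__(
        self,
        fast_threshold: int = 20,
        fast_min_count: int = 9,
        patch_size: int = 31,
        n_bits: int = 256,
        smoothing_sigma: float = 2.0,
        n_pyramid_levels: int = 1,
        pyramid_scale: float = 1.2,
        max_keypoints: int | None = None,
        nms_window: int = 5,
        contiguous_arc: bool = False,
        pattern_seed: int = DEFAULT_PATTERN_SEED,
    ):
        self.fast_threshold = fast_threshold
        self.fast_min_count = fast_min_count
        self.patch_size = patch_size
        self.n_bits = n_bits
        self.smoothing_sigma = smoothing_sigma
        self.n_pyramid_levels = n_pyramid_levels
        self.pyramid_scale = pyramid_scale
        self.max_keypoints = max_keypoints
        self.nms_window = nms_window
        self.contiguous_arc = contiguous_arc
        self.pattern_seed = pattern_seed

    def _config(self) -> OrbConfig:
        return OrbConfig(
            fast_threshold=self.fast_threshold,
            fast_min_count=self.fast_min_count,
            patch_size=self.patch_size,
            n_bits=self.n_bits,
            smoothing_sigma=self.smoothing_sigma,
            n_pyramid_levels=self.n_pyramid_levels,
            pyramid_scale=self.pyramid_scale,
            max_keypoints=self.max_keypoints,
            nms_window=self.nms_window,
            contiguous_arc=self.contiguous_arc,
        )

    def fit(self, X=None, y=None) -> "OrbFeatureExtractor":
        self.config_ = self._config()
        self.pattern_ = default_pattern(self.config_, self.pattern_seed)
        return self

    def extract_frame(self, frame) -> tuple[list[KeyPoint], np.ndarray]:
        if not hasattr(self, "pattern_"):
            self.fit()
        return extract(frame, self.config_, self.pattern_)

    def transform(self, X: Sequence) -> list[np.ndarray]:
        return [self.extract_frame(f)[1] for f in X]

    def keypoint_counts(self, X: Sequence) -> np.ndarray:
        """Number of detected keypoints per frame (the peak-count proxy)."""
        return np.array([len(self.extract_frame(f)[0]) for f in X], dtype=int)
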