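"""Shared fixtures: small simulated datasets and a fitted extractor.

Everything is generated at test time from fixed seeds; session scope
amortises the simulation and extraction cost across test modules.
"""

import numpy as np
import pytest

from braggveto import OrbFeatureExtractor, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def extractor() -> OrbFeatureExtractor:
    return OrbFeatureExtractor().fit()


@pytest.fixture(scope="session")
def small_dataset():
    """30 hits + 30 misses at default SNR, with truth labels."""
    frames = generate_dataset(SimConfig(n_hit=30, n_miss=30, seed=101))
    labels = np.array([f.truth_label for f in frames])
    return frames, labels


@pytest.fixture(scope="session")
def small_descriptors(small_dataset, extractor):
    """Per-frame packed descriptors and keypoint counts for small_dataset."""
    frames, labels = small_dataset
    keypoints, descriptors = [], []
    for fr in frames:
        k, d = extractor.extract_frame(fr)
        keypoints.append(k)
        descriptors.append(d)
    counts = np.array([len(k) for k in keypoints])
    return descriptors, counts, labels


@pytest.fixture(scope="session")
def bovw_features(small_descriptors):
    from braggveto.bovw import BovwEncoder

    descriptors, counts, labels = small_descriptors
    enc = BovwEncoder(n_classes=2, random_state=0).fit(descriptors)
    return enc.transform(descriptors), labels


@pytest.fixture(scope="session")
def null_features(extractor):
    """200 balanced frames encoded as BoVW features, for permutation nulls.

    Chance-level tests need enough frames that the 20-repeat mean accuracy
    concentrates well inside the +/-3 point band.
    """
    from braggveto.bovw import BovwEncoder

    frames = generate_dataset(SimConfig(n_hit=100, n_miss=100, seed=202))
    labels = np.array([f.truth_label for f in frames])
    descriptors = extractor.transform(frames)
    enc = BovwEncoder(n_classes=2, random_state=0).fit(descriptors)
    return enc.transform(descriptors), labels
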