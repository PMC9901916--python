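"""File formats: facility-independent HDF5 frame stacks, TIFF fixtures,
descriptor/keypoint/codebook containers and CSV label tables.

The HDF5 layout mirrors the reduced-data convention used by hit-finding
preprocessors: a 3-D stack at ``/data/data`` (frame, row, col), optional
``/data/mask``, integer labels at ``/data/truth_labels`` (0 = miss,
1 = hit) and per-frame ground-truth peak tables under
``/truth/peaks/<index>`` when frames are simulated.
"""

from __future__ import annotations

import struct
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bovw import BoVWConfig, Codebook
from .simulator import HIT, MISS, DiffractionFrame

DATA_PATH = "/data/data"
MASK_PATH = "/data/mask"
LABEL_PATH = "/data/truth_labels"
PEAKS_GROUP = "/truth/peaks"

_DESC_MAGIC = b"BVDS"


# ---------------------------------------------------------------------------
# HDF5 frame stacks
# ---------------------------------------------------------------------------

def write_frames(path: str | Path, frames: list[DiffractionFrame]) -> None:
    """Write a dataset of frames to the facility-independent HDF5 layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        stack = np.stack([fr.intensities for fr in frames])
        f.create_dataset(DATA_PATH, data=stack)
        masks = [
            fr.mask if fr.mask is not None else np.ones(fr.shape, dtype=bool)
            for fr in frames
        ]
        f.create_dataset(MASK_PATH, data=np.stack(masks))
        if all(fr.truth_label is not None for fr in frames):
            labels = np.array([1 if fr.truth_label == HIT else 0 for fr in frames])
            f.create_dataset(LABEL_PATH, data=labels.astype(np.int8))
        grp = f.create_group(PEAKS_GROUP)
        for i, fr in enumerate(frames):
            grp.create_dataset(str(i), data=fr.truth_peaks)


def read_frames(path: str | Path, fmt: str | None = None) -> list[DiffractionFrame]:
    """Load frames from HDF5 (or a single-frame TIFF/PNG fixture).

    The format is inferred from the extension unless ``fmt`` is given.
    Malformed files raise errors naming the offending dataset path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {
            ".h5": "hdf5", ".hdf5": "hdf5", ".tif": "tiff", ".tiff": "tiff",
            ".png": "png",
        }.get(path.suffix.lower(), "hdf5")
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt in ("tiff", "png"):
        return [_read_image(path)]
    raise ValueError(f"unknown format {fmt!r}")


def _read_hdf5(path: Path) -> list[DiffractionFrame]:
    with h5py.File(path, "r") as f:
        if DATA_PATH not in f:
            raise KeyError(f"{path}: missing dataset {DATA_PATH}")
        stack = f[DATA_PATH][...]
        if stack.ndim != 3:
            raise ValueError(
                f"{path}:{DATA_PATH} must be a 3-D (frame, row, col) stack, "
                f"got shape {stack.shape}"
            )
        if np.any(stack < 0):
            raise ValueError(f"{path}:{DATA_PATH} contains negative intensities")
        masks = f[MASK_PATH][...] if MASK_PATH in f else None
        labels = f[LABEL_PATH][...] if LABEL_PATH in f else None
        peaks = {}
        if PEAKS_GROUP in f:
            for key in f[PEAKS_GROUP]:
                peaks[int(key)] = f[PEAKS_GROUP][key][...]
    frames = []
    for i in range(stack.shape[0]):
        mask = None
        if masks is not None and not masks[i].all():
            mask = masks[i].astype(bool)
        label = None
        if labels is not None:
            label = HIT if labels[i] else MISS
        frames.append(
            DiffractionFrame(
                intensities=stack[i].astype(np.float64),
                mask=mask,
                truth_peaks=peaks.get(i, np.empty((0, 2))),
                truth_label=label,
            )
        )
    return frames


def _read_image(path: Path) -> DiffractionFrame:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D frame, got shape {img.shape}")
    return DiffractionFrame(intensities=img.astype(np.float64))


def write_tiff(path: str | Path, frame: DiffractionFrame) -> None:
    """Export one frame as 16-bit TIFF (intensities clipped to uint16)."""
    import tifffile

    data = np.clip(frame.intensities, 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(Path(path), data.astype(np.uint16))


# ---------------------------------------------------------------------------
# descriptor / keypoint containers
# ---------------------------------------------------------------------------

def write_descriptors(path: str | Path, descriptor_lists: list[np.ndarray]) -> None:
    """Binary container: magic, n_bits, per-frame counts, packed bits."""
    arrays = [np.asarray(d, dtype=np.uint8) for d in descriptor_lists]
    n_bytes = next((a.shape[1] for a in arrays if a.size), 32)
    with open(path, "wb") as f:
        f.write(_DESC_MAGIC)
        f.write(struct.pack("<II", n_bytes * 8, len(arrays)))
        for a in arrays:
            f.write(struct.pack("<I", len(a)))
            f.write(a.tobytes())


def read_descriptors(path: str | Path) -> list[np.ndarray]:
    with open(path, "rb") as f:
        magic = f.read(4)
        if magic != _DESC_MAGIC:
            raise ValueError(f"{path}: not a descriptor container")
        n_bits, n_frames = struct.unpack("<II", f.read(8))
        n_bytes = n_bits // 8
        out = []
        for _ in range(n_frames):
            (count,) = struct.unpack("<I", f.read(4))
            buf = f.read(count * n_bytes)
            out.append(np.frombuffer(buf, dtype=np.uint8).reshape(count, n_bytes).copy())
    return out


def write_keypoints_csv(path: str | Path, keypoints_per_frame: list[list]) -> None:
    rows = [
        {
            "frame_index": i,
            "row": kp.row,
            "col": kp.col,
            "score": kp.score,
            "theta": kp.theta,
        }
        for i, kps in enumerate(keypoints_per_frame)
        for kp in kps
    ]
    pd.DataFrame(rows, columns=["frame_index", "row", "col", "score", "theta"]).to_csv(
        path, index=False
    )


def write_labels_csv(path: str | Path, labels, counts=None) -> None:
    df = pd.DataFrame({"frame_index": np.arange(len(labels)), "label": list(labels)})
    if counts is not None:
        df["keypoint_count"] = np.asarray(counts, dtype=int)
    df.to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    return df


# ---------------------------------------------------------------------------
# codebook persistence
# ---------------------------------------------------------------------------

def write_codebook(path: str | Path, codebook: Codebook) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("centers", data=codebook.centers)
        f.attrs["n_classes"] = codebook.config.n_classes
        f.attrs["max_iterations"] = codebook.config.max_iterations
        f.attrs["tol"] = codebook.config.tol
        f.attrs["seed"] = codebook.config.seed
        f.attrs["training_descriptor_count"] = codebook.training_descriptor_count


def read_codebook(path: str | Path) -> Codebook:
    with h5py.File(path, "r") as f:
        if "centers" not in f:
            raise KeyError(f"{path}: missing 'centers' dataset")
        centers = f["centers"][...]
        config = BoVWConfig(
            n_classes=int(f.attrs["n_classes"]),
            max_iterations=int(f.attrs["max_iterations"]),
            tol=float(f.attrs["tol"]),
            seed=int(f.attrs["seed"]),
        )
        count = int(f.attrs["training_descriptor_count"])
    return Codebook(centers=centers, config=config, training_descriptor_count=count)
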