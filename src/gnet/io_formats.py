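"""Readers and writers for the formats the tool touches.

* NIfTI (``.nii`` / ``.nii.gz``) volumes via nibabel, sliced axially along the
  last axis with the affine preserved.
* 16-bit grayscale PNG for 2-D images (intensities scaled to [0, 65535]) and
  label masks (stored verbatim, hence lossless).
* CSV dataset manifests mapping image/mask paths to train/val/test splits,
  with an optional subject column for subject-level splitting.

Coordinate convention: row-major, origin top-left, 0-based indexing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .exceptions import ConfigurationError, DataError, ShapeError

__all__ = [
    "VolumeStack",
    "DatasetManifest",
    "read_volume",
    "write_volume",
    "read_image_png",
    "write_image_png",
    "read_mask_png",
    "write_mask_png",
    "remap_labels",
    "normalize_rescale",
    "write_prediction",
    "read_prediction",
    "load_manifest",
    "write_phantom_dataset",
    "BRATS_LABEL_MAP",
]

BRATS_LABEL_MAP = {0: 0, 1: 1, 2: 2, 4: 3}
PNG_SCALE = 65535


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

@dataclass
class VolumeStack:
    """An ordered stack of same-sized 2-D slices with spatial metadata."""

    data: np.ndarray                     # (H, W, S)
    affine: np.ndarray = None
    modality: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"volume must be (H, W, S), got {self.data.shape}")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def slices(self) -> list[np.ndarray]:
        """Axial slices as (H, W, 1) images."""
        return [self.data[:, :, i][..., None] for i in range(self.n_slices)]


def read_volume(path, modality: str = "unknown") -> VolumeStack:
    """Read a NIfTI volume; slices are taken along the last (axial) axis."""
    path = str(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise DataError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    if data.ndim != 3:
        raise DataError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    return VolumeStack(data=data, affine=np.asarray(img.affine), modality=modality)


def write_volume(volume: VolumeStack, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume.data), volume.affine), str(path))


# --------------------------------------------------------------------------
# 2-D PNG images and masks
# --------------------------------------------------------------------------

def write_image_png(img: np.ndarray, path) -> None:
    """Write a float image in [0, 1] as 16-bit grayscale PNG."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3 and img.shape[-1] == 1:
        img = img[..., 0]
    if img.ndim != 2:
        raise ShapeError(f"PNG writer expects a single-channel image: {img.shape}")
    if img.min() < 0 or img.max() > 1:
        raise DataError("image intensities must lie in [0, 1] for PNG export")
    arr = np.round(img * PNG_SCALE).astype(np.uint16)
    Image.fromarray(arr).save(str(path))


def read_image_png(path) -> np.ndarray:
    """Read a 16-bit grayscale PNG back to a float (H, W, 1) image in [0, 1]."""
    arr = np.asarray(Image.open(str(path)), dtype=np.float32) / PNG_SCALE
    return arr[..., None]


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write an integer label mask losslessly as 16-bit PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ShapeError(f"mask must be 2-D, got {mask.shape}")
    if mask.min() < 0 or mask.max() > PNG_SCALE:
        raise DataError("labels must fit in uint16")
    Image.fromarray(mask.astype(np.uint16)).save(str(path))


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(str(path)), dtype=np.int64)


# --------------------------------------------------------------------------
# label remapping and normalization
# --------------------------------------------------------------------------

def remap_labels(mask: np.ndarray, mapping: dict[int, int] | None = None) -> np.ndarray:
    """Pixelwise label substitution; default maps BraTS {0,1,2,4} to 0..3."""
    mapping = mapping if mapping is not None else BRATS_LABEL_MAP
    mask = np.asarray(mask)
    present = np.unique(mask)
    unmapped = sorted(int(v) for v in present if int(v) not in mapping)
    if unmapped:
        raise DataError(f"mask contains unmapped labels: {unmapped}")
    lut = np.zeros(int(present.max()) + 1, dtype=np.int64)
    for src, dst in mapping.items():
        if src <= present.max():
            lut[src] = dst
    return lut[mask]


def normalize_rescale(img: np.ndarray, target: tuple[int, int],
                      method: str = "minmax") -> np.ndarray:
    """Per-slice intensity normalization plus bilinear resize.

    ``method="minmax"`` scales to [0, 1] (constant slices map to all zeros);
    ``method="zscore"`` standardizes to zero mean and unit variance. Resizing
    to the input's own size is the identity.
    """
    img = np.asarray(img, dtype=np.float64)
    squeeze = False
    if img.ndim == 2:
        img = img[..., None]
        squeeze = True
    if img.ndim != 3:
        raise ShapeError(f"expected (H, W[, C]) image, got {img.shape}")
    th, tw = target
    if th < 2 or tw < 2:
        raise ConfigurationError(f"target size too small: {target}")
    if method == "minmax":
        lo, hi = img.min(), img.max()
        img = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    elif method == "zscore":
        sd = img.std()
        img = np.zeros_like(img) if sd == 0 else (img - img.mean()) / sd
    else:
        raise ConfigurationError(f"unknown normalization method {method!r}")
    if img.shape[:2] != (th, tw):
        img = resize(img, (th, tw), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    out = img.astype(np.float32)
    return out[..., 0] if squeeze else out


def filter_blank_slices(images: np.ndarray, masks: np.ndarray,
                        intensity_eps: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Drop slices whose mask is empty AND whose intensity range is ~zero.

    Useful when slicing full volumes, where the outermost axial slices carry
    no brain tissue. Off by default everywhere; call explicitly to enable.
    """
    images = np.asarray(images)
    masks = np.asarray(masks)
    if len(images) != len(masks):
        raise ShapeError("images and masks must have matching leading dims")
    keep = [
        bool(masks[i].any())
        or float(images[i].max() - images[i].min()) > intensity_eps
        for i in range(len(images))
    ]
    return images[keep], masks[keep]


# --------------------------------------------------------------------------
# predictions
# --------------------------------------------------------------------------

def write_prediction(arr: np.ndarray, path, format: str = "auto") -> None:
    """Write a hard label mask (PNG or NIfTI) or probability map (NIfTI).

    ``format``: "png", "nifti", or "auto" (inferred from the extension).
    """
    path = str(path)
    arr = np.asarray(arr)
    if format == "auto":
        if path.endswith(".png"):
            format = "png"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise ConfigurationError(
                f"cannot infer format from {path!r}; pass format= explicitly")
    if format == "png":
        if arr.ndim != 2:
            raise ShapeError("PNG predictions must be 2-D label masks")
        write_mask_png(arr, path)
    elif format == "nifti":
        if arr.ndim == 2:  # label mask
            data = arr.astype(np.int16)[..., None]
        elif arr.ndim == 3:  # (H, W, K) probability map
            data = arr.astype(np.float32)
        else:
            raise ShapeError(f"unsupported prediction shape {arr.shape}")
        nib.save(nib.Nifti1Image(data, np.eye(4)), path)
    else:
        raise ConfigurationError(f"unsupported format {format!r}")


def read_prediction(path) -> np.ndarray:
    path = str(path)
    if path.endswith(".png"):
        return read_mask_png(path)
    if path.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(path).dataobj)
        if data.ndim == 3 and data.shape[-1] == 1 and np.issubdtype(
                data.dtype, np.integer):
            return data[..., 0].astype(np.int64)
        return data
    raise ConfigurationError(f"unsupported prediction file {path!r}")


# --------------------------------------------------------------------------
# dataset manifests
# --------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Paths and split assignment for a 2-D segmentation dataset."""

    root: Path
    records: pd.DataFrame  # columns: path_image, path_mask, split [, subject]

    SPLITS = ("train", "val", "test")

    def __post_init__(self):
        self.root = Path(self.root)
        required = {"path_image", "path_mask", "split"}
        missing = required - set(self.records.columns)
        if missing:
            raise DataError(f"manifest missing columns: {sorted(missing)}")
        bad = set(self.records["split"]) - set(self.SPLITS)
        if bad:
            raise DataError(f"unknown split tags: {sorted(bad)}")
        dup = self.records["path_image"].duplicated()
        if dup.any():
            raise DataError("an image path appears in more than one record")

    def paths(self, split: str) -> list[tuple[Path, Path]]:
        sub = self.records[self.records["split"] == split]
        return [(self.root / r.path_image, self.root / r.path_mask)
                for r in sub.itertuples()]

    def counts(self) -> dict[str, int]:
        return {s: int((self.records["split"] == s).sum()) for s in self.SPLITS}

    def load_split(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        """Load a split into ``(images (n, H, W, 1), masks (n, H, W))``."""
        imgs, masks = [], []
        for img_path, mask_path in self.paths(split):
            imgs.append(read_image_png(img_path))
            masks.append(read_mask_png(mask_path))
        if not imgs:
            raise DataError(f"split {split!r} is empty")
        return np.stack(imgs), np.stack(masks)

    def validate_files(self) -> None:
        for r in self.records.itertuples():
            for p in (self.root / r.path_image, self.root / r.path_mask):
                if not p.exists():
                    raise DataError(f"manifest references missing file {p}")

    def save(self, path=None) -> Path:
        path = Path(path) if path is not None else self.root / "manifest.csv"
        self.records.to_csv(path, index=False)
        return path


def load_manifest(path) -> DatasetManifest:
    path = Path(path)
    manifest = DatasetManifest(root=path.parent, records=pd.read_csv(path))
    manifest.validate_files()
    return manifest


def write_phantom_dataset(spec, n: int, split_tags: list[str],
                          out_dir) -> DatasetManifest:
    """Materialize ``n`` phantoms of ``spec`` as PNG pairs plus a manifest."""
    from .synthetic_data import generate_phantom

    out_dir = Path(out_dir)
    for sub in ("images", "masks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        pair = generate_phantom(spec, i)
        img_rel = f"images/phantom_{i:05d}.png"
        mask_rel = f"masks/phantom_{i:05d}.png"
        write_image_png(pair.image[..., 0], out_dir / img_rel)
        write_mask_png(pair.mask, out_dir / mask_rel)
        rows.append({"path_image": img_rel, "path_mask": mask_rel,
                     "split": split_tags[i]})
    manifest = DatasetManifest(root=out_dir, records=pd.DataFrame(rows))
    manifest.save()
    return manifest
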