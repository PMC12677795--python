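"""Image I/O and preprocessing: resizing, intensity normalisation,
augmentation, and the train/test split.

Images are 2-D grayscale. Raw images carry an explicit bit depth (8, 12 or
16); normalisation maps them into [0, 1] either by dividing by 2^bit_depth
(``paper_literal``, the default) or by the true maximum 2^bit_depth - 1
(``max_value``). Augmentation applies one randomly chosen geometric or
photometric transform per new sample, identically to the MRI, PET and mask
channels so co-registration is preserved by construction; each augmented pair
records the transform that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import nibabel as nib
from skimage import transform as sktf

__all__ = [
    "RawImage",
    "ImagePair",
    "DatasetSplit",
    "resize_image",
    "normalize_intensity",
    "augment_dataset",
    "apply_transform",
    "split_dataset",
    "read_raw_image",
    "read_mask",
    "write_image_png",
    "write_mask_png",
    "write_dataset",
    "read_dataset",
]

_VALID_BIT_DEPTHS = (8, 12, 16)


@dataclass(frozen=True)
class RawImage:
    """Integer-valued 2-D image with an explicit bit depth."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.bit_depth not in _VALID_BIT_DEPTHS:
            raise ValueError(f"bit depth must be one of {_VALID_BIT_DEPTHS}")
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if p.min() < 0 or p.max() > 2 ** self.bit_depth - 1:
            raise ValueError(f"intensities outside [0, {2**self.bit_depth - 1}]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ImagePair:
    """One co-registered, normalised MRI/PET slice pair with optional mask."""

    mri: np.ndarray
    pet: np.ndarray
    id: str
    mask: np.ndarray | None = None
    transform: dict | None = None  # provenance of an augmented copy

    def __post_init__(self) -> None:
        if self.mri.shape != self.pet.shape:
            raise ValueError("MRI and PET must share dimensions")
        for name, im in (("mri", self.mri), ("pet", self.pet)):
            if im.min() < 0 or im.max() > 1:
                raise ValueError(f"{name} must be normalised to [0, 1]")
        if self.mask is not None:
            if self.mask.shape != self.mri.shape:
                raise ValueError("mask must share image dimensions")
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask values must be in {0, 1}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mri.shape


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def resize_image(img: RawImage, target_h: int, target_w: int) -> RawImage:
    """Bilinear resize, clamped back to the input bit-depth range."""
    if target_h < 1 or target_w < 1:
        raise ValueError(f"target dimensions must be >= 1, got {target_h}x{target_w}")
    if (target_h, target_w) == (img.height, img.width):
        return img
    out = sktf.resize(img.pixels.astype(float), (target_h, target_w), order=1,
                      mode="edge", anti_aliasing=False, preserve_range=True)
    out = np.clip(np.rint(out), 0, 2 ** img.bit_depth - 1)
    return RawImage(pixels=out.astype(img.pixels.dtype), bit_depth=img.bit_depth)


def normalize_intensity(img: RawImage, mode: str = "paper_literal") -> np.ndarray:
    """Map intensities into [0, 1].

    ``paper_literal`` divides by 2^bit_depth (256 for 8-bit images);
    ``max_value`` divides by the attainable maximum 2^bit_depth - 1, so the
    brightest representable pixel maps exactly to 1.
    """
    if mode == "paper_literal":
        divisor = float(2 ** img.bit_depth)
    elif mode == "max_value":
        divisor = float(2 ** img.bit_depth - 1)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return img.pixels.astype(float) / divisor


# ---------------------------------------------------------------------------
# augmentation

_TRANSFORM_FAMILIES = ("rotate", "hflip", "vflip", "zoom", "brightness", "shift")


def _sample_transform(rng: np.random.Generator) -> dict:
    kind = _TRANSFORM_FAMILIES[rng.integers(len(_TRANSFORM_FAMILIES))]
    if kind == "rotate":
        return {"kind": kind, "angle": float(rng.uniform(-15.0, 15.0))}
    if kind == "zoom":
        return {"kind": kind, "factor": float(rng.uniform(0.9, 1.1))}
    if kind == "brightness":
        return {"kind": kind, "scale": float(rng.uniform(0.9, 1.1))}
    if kind == "shift":
        return {"kind": kind,
                "dy": int(rng.integers(-10, 11)), "dx": int(rng.integers(-10, 11))}
    return {"kind": kind}


def _warp_channel(im: np.ndarray, tfm: dict, is_mask: bool) -> np.ndarray:
    order = 0 if is_mask else 1
    kind = tfm["kind"]
    if kind == "rotate":
        out = sktf.rotate(im.astype(float), tfm["angle"], order=order,
                          mode="constant", cval=0.0, preserve_range=True)
    elif kind == "hflip":
        out = im[:, ::-1].astype(float)
    elif kind == "vflip":
        out = im[::-1, :].astype(float)
    elif kind == "zoom":
        h, w = im.shape
        centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        f = tfm["factor"]
        t = (sktf.SimilarityTransform(translation=-centre)
             + sktf.SimilarityTransform(scale=f)
             + sktf.SimilarityTransform(translation=centre))
        out = sktf.warp(im.astype(float), t.inverse, order=order,
                        mode="constant", cval=0.0, preserve_range=True)
    elif kind == "shift":
        t = sktf.SimilarityTransform(translation=(tfm["dx"], tfm["dy"]))
        out = sktf.warp(im.astype(float), t.inverse, order=order,
                        mode="constant", cval=0.0, preserve_range=True)
    elif kind == "brightness":
        out = im.astype(float) if is_mask else np.clip(im * tfm["scale"], 0.0, 1.0)
    else:
        raise ValueError(f"unknown transform {kind!r}")
    if is_mask:
        out = (out >= 0.5).astype(np.uint8)  # re-binarize after warping
    else:
        out = np.clip(out, 0.0, 1.0)
    return out


def apply_transform(pair: ImagePair, tfm: dict, new_id: str | None = None) -> ImagePair:
    """Apply one recorded transform identically to MRI, PET and mask."""
    mask = None if pair.mask is None else _warp_channel(pair.mask, tfm, is_mask=True)
    return ImagePair(
        mri=_warp_channel(pair.mri, tfm, is_mask=False),
        pet=_warp_channel(pair.pet, tfm, is_mask=False),
        mask=mask,
        id=new_id or f"{pair.id}_aug",
        transform=tfm,
    )


def augment_dataset(pairs: list[ImagePair], target_n: int, seed: int) -> list[ImagePair]:
    """Grow a dataset to ``target_n`` pairs with seeded random transforms.

    Originals are retained unchanged; each new pair is a transformed copy of a
    randomly chosen original, with the same transform applied to all channels.
    """
    n = len(pairs)
    if target_n < n:
        raise ValueError(f"target_n ({target_n}) must be >= input count ({n})")
    if target_n == n:
        return list(pairs)
    rng = np.random.default_rng(seed)
    out = list(pairs)
    for j in range(target_n - n):
        src = pairs[int(rng.integers(n))]
        tfm = _sample_transform(rng)
        out.append(apply_transform(src, tfm, new_id=f"{src.id}_aug{j}"))
    return out


def split_dataset(ids: list[str], train_n: int, seed: int) -> DatasetSplit:
    """Seeded shuffle split into ``train_n`` training ids and the remainder."""
    if train_n > len(ids):
        raise ValueError(f"train_n ({train_n}) exceeds available ids ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return DatasetSplit(train_ids=order[:train_n], test_ids=order[train_n:])


# ---------------------------------------------------------------------------
# readers / writers

def read_raw_image(path: str | Path, slice_index: int | None = None) -> RawImage:
    """Read a grayscale PNG (8/16-bit) or a NIfTI slice as a RawImage."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        vol = np.asarray(nib.load(str(path)).dataobj)
        if vol.ndim == 3:
            vol = vol[:, :, slice_index if slice_index is not None else 0]
        data = np.asarray(vol, dtype=float)
        data = np.clip(np.rint(data), 0, None)
        depth = 8 if data.max() <= 255 else 16
        return RawImage(pixels=data.astype(np.uint16), bit_depth=depth)
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1).round().astype(arr.dtype)
    depth = 16 if arr.dtype == np.uint16 else 8
    return RawImage(pixels=arr, bit_depth=depth)


def read_mask(path: str | Path, slice_index: int | None = None) -> np.ndarray:
    """Read a binary mask from PNG ({0, 255}) or NIfTI ({0, 1})."""
    raw = read_raw_image(path, slice_index)
    return (raw.pixels > 0).astype(np.uint8)


def write_image_png(path: str | Path, image: np.ndarray) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (np.rint(arr * 255)).astype(np.uint8))


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=np.uint8) * 255))


def write_dataset(pairs: list[ImagePair], out_dir: str | Path) -> None:
    """Write pairs to mri/, pet/, mask/ PNG subfolders plus a manifest."""
    out = Path(out_dir)
    for sub in ("mri", "pet", "mask"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest = []
    for p in pairs:
        write_image_png(out / "mri" / f"{p.id}.png", p.mri)
        write_image_png(out / "pet" / f"{p.id}.png", p.pet)
        entry = {"id": p.id, "has_mask": p.mask is not None}
        if p.mask is not None:
            write_mask_png(out / "mask" / f"{p.id}.png", p.mask)
        manifest.append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(in_dir: str | Path, normalize: str = "max_value") -> list[ImagePair]:
    """Read a dataset written by :func:`write_dataset` (or the same layout)."""
    root = Path(in_dir)
    manifest_path = root / "manifest.json"
    if manifest_path.exists():
        entries = json.loads(manifest_path.read_text())
        ids = [e["id"] for e in entries]
    else:
        ids = sorted(p.stem for p in (root / "mri").glob("*.png"))
    pairs = []
    for pid in ids:
        mri = normalize_intensity(read_raw_image(root / "mri" / f"{pid}.png"), normalize)
        pet = normalize_intensity(read_raw_image(root / "pet" / f"{pid}.png"), normalize)
        mask_path = root / "mask" / f"{pid}.png"
        mask = read_mask(mask_path) if mask_path.exists() else None
        pairs.append(ImagePair(mri=mri, pet=pet, mask=mask, id=pid))
    return pairs
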