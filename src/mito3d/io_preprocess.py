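"""Stack I/O, per-slice histogram equalization, patch extraction, augmentation.

Serial-section EM stacks arrive as multi-page TIFF or HDF5 volumes. Brightness
drifts from section to section (beam instability, uneven surfaces), so contrast
normalisation is applied independently per z-slice. Training samples are small
3D patches tiled deterministically from the stack, each optionally expanded by
the 16-element symmetry group of in-plane rotations and xy/z flips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import tifffile

from .volume import LabelVolume, VoxelSpacing, Volume

__all__ = [
    "PatchSpec",
    "AugTransform",
    "AUGMENTATIONS",
    "read_stack",
    "write_stack",
    "equalize_histogram",
    "extract_patches",
    "apply_augmentation",
]

_HDF5_DATASET = "volume"
_SPACING_ATTR = "spacing_nm"


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ValueError(f"cannot infer format from {path}; pass format='tiff'|'hdf5'")


def read_stack(
    path: str | Path,
    format: str | None = None,
    spacing: VoxelSpacing | None = None,
) -> Volume:
    """Read a grayscale stack into a (z, y, x) :class:`Volume`.

    HDF5 files carry their spacing in the ``spacing_nm`` attribute; for TIFF
    (or HDF5 files without the attribute) ``spacing`` must be supplied.
    Intensities are returned unmodified.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tiff":
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - surfaced as a format error
            raise ValueError(f"could not decode TIFF stack {path}: {exc}") from exc
    elif fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            if _HDF5_DATASET not in fh:
                raise ValueError(f"{path} has no '{_HDF5_DATASET}' dataset")
            dset = fh[_HDF5_DATASET]
            data = dset[()]
            if spacing is None and _SPACING_ATTR in dset.attrs:
                sz, sy, sx = (float(v) for v in dset.attrs[_SPACING_ATTR])
                spacing = VoxelSpacing(sz, sy, sx)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path} decodes to shape {data.shape}; multichannel/RGB stacks are unsupported"
        )
    if spacing is None:
        raise ValueError(f"no spacing stored in {path}; pass spacing=VoxelSpacing(...)")
    return Volume(data, spacing)


def write_stack(
    volume: Volume | LabelVolume,
    path: str | Path,
    format: str | None = None,
    quantize: bool = False,
) -> None:
    """Write a volume or label stack; integer round-trips are bit-exact.

    Float data (probability maps) is refused for TIFF unless ``quantize=True``,
    which rescales [0, 1] to the full 8-bit range — never silently.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    data = volume.data
    if fmt == "tiff":
        if np.issubdtype(data.dtype, np.floating):
            if not quantize:
                raise ValueError(
                    "refusing lossy float->integer TIFF conversion; pass quantize=True"
                )
            data = np.clip(np.round(data * 255.0), 0, 255).astype(np.uint8)
        tifffile.imwrite(path, data, photometric="minisblack")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset(_HDF5_DATASET, data=data)
            dset.attrs[_SPACING_ATTR] = list(volume.spacing.as_tuple())
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_labels(
    path: str | Path,
    format: str | None = None,
    spacing: VoxelSpacing | None = None,
    semantics: str = "binary",
) -> LabelVolume:
    """Read an integer label stack (binary mask or instance labeling)."""
    vol = read_stack(path, format=format, spacing=spacing)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(f"{path} holds {data.dtype} data, expected integer labels")
    return LabelVolume(data, vol.spacing, semantics=semantics)


# ---------------------------------------------------------------------------
# histogram equalization
# ---------------------------------------------------------------------------

def _equalize_slice(img: np.ndarray, n_levels: int) -> np.ndarray:
    """Classic CDF remap of one slice onto [0, n_levels - 1]."""
    flat = img.ravel()
    hist = np.bincount(flat, minlength=n_levels)
    cdf = np.cumsum(hist)
    nonzero = cdf[cdf > 0]
    if nonzero.size == 0:
        return img
    cdf_min = nonzero[0]
    total = cdf[-1]
    if total == cdf_min:
        # constant slice: nothing to spread
        return img
    lut = np.round((cdf - cdf_min) / (total - cdf_min) * (n_levels - 1))
    lut = np.clip(lut, 0, n_levels - 1).astype(img.dtype)
    return lut[img]


def equalize_histogram(volume: Volume, mode: str = "per_slice", n_levels: int = 256) -> Volume:
    """Global CDF histogram equalization, applied independently per z-slice.

    Per-slice application is the point: it removes the section-to-section
    brightness drift of serial-section stacks, so two slices with identical
    content but different offsets equalize to the same image. The mapping is
    monotone within each slice and leaves constant slices untouched.
    """
    if mode not in ("per_slice", "global"):
        raise ValueError(f"unknown equalization mode {mode!r}")
    data = volume.data
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError("histogram equalization expects an integer-typed volume")
    if data.min() < 0 or data.max() >= n_levels:
        raise ValueError(f"intensities must lie in [0, {n_levels - 1}]")
    if mode == "global":
        flat_eq = _equalize_slice(data, n_levels)
        return volume.with_data(flat_eq)
    out = np.empty_like(data)
    for z in range(data.shape[0]):
        out[z] = _equalize_slice(data[z], n_levels)
    return volume.with_data(out)


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchSpec:
    """Patch shape and stride in voxels, (z, y, x).

    ``stride=None`` means non-overlapping tiling (stride = shape). The final
    patch along each axis is shifted inward to end flush with the volume edge,
    so every voxel is covered without zero padding.
    """

    shape: tuple[int, int, int]
    stride: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError(f"patch shape must be positive, got {self.shape}")
        if self.stride is not None and any(
            not (1 <= st <= sh) for st, sh in zip(self.stride, self.shape)
        ):
            raise ValueError(
                f"stride must be in [1, patch size] per axis, got {self.stride} for {self.shape}"
            )

    @property
    def effective_stride(self) -> tuple[int, int, int]:
        return self.stride if self.stride is not None else self.shape


def _axis_starts(dim: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, dim - patch + 1, stride))
    if starts[-1] + patch < dim:
        starts.append(dim - patch)  # flush final patch
    return starts


def patch_origins(shape: tuple[int, int, int], spec: PatchSpec) -> list[tuple[int, int, int]]:
    """Deterministic z-major, then y, then x list of patch origin corners."""
    for axis, (dim, p) in enumerate(zip(shape, spec.shape)):
        if p > dim:
            raise ValueError(
                f"patch size {p} exceeds volume extent {dim} on axis {'zyx'[axis]}"
            )
    stz, sty, stx = spec.effective_stride
    zs = _axis_starts(shape[0], spec.shape[0], stz)
    ys = _axis_starts(shape[1], spec.shape[1], sty)
    xs = _axis_starts(shape[2], spec.shape[2], stx)
    return [(z, y, x) for z in zs for y in ys for x in xs]


def extract_patches(
    volume: Volume,
    labels: LabelVolume | None,
    spec: PatchSpec,
) -> Iterator[tuple[np.ndarray, np.ndarray | None]]:
    """Yield (patch, label_patch) pairs tiling the volume in z-major order."""
    if labels is not None and labels.shape != volume.shape:
        raise ValueError(
            f"volume shape {volume.shape} and label shape {labels.shape} differ"
        )
    pz, py, px = spec.shape
    for z, y, x in patch_origins(volume.shape, spec):
        img = volume.data[z : z + pz, y : y + py, x : x + px]
        lab = None
        if labels is not None:
            lab = labels.data[z : z + pz, y : y + py, x : x + px]
        yield img, lab


# ---------------------------------------------------------------------------
# the 16-element augmentation group
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugTransform:
    """One element of the augmentation group: rotation about z, xy-flip, z-flip.

    ``rotation`` is degrees counter-clockwise in the xy-plane, one of
    {-90, 0, 90, 180}; the flip over the xy-plane mirrors the y axis and the
    z-flip reverses the section order. The 16 combinations form a group closed
    under inversion (rotation applied first, then flips).
    """

    rotation: int = 0
    flip_xy: bool = False
    flip_z: bool = False

    _ROT_K = {0: 0, 90: 1, 180: 2, -90: 3}

    def __post_init__(self) -> None:
        if self.rotation not in self._ROT_K:
            raise ValueError(f"rotation must be one of {sorted(self._ROT_K)}, got {self.rotation}")

    def apply(self, arr: np.ndarray) -> np.ndarray:
        """Apply to a (z, y, x) array; pure index permutation, no resampling."""
        out = np.rot90(arr, k=self._ROT_K[self.rotation], axes=(1, 2))
        if self.flip_xy:
            out = out[:, ::-1, :]
        if self.flip_z:
            out = out[::-1, :, :]
        return np.ascontiguousarray(out)

    def inverse(self) -> "AugTransform":
        # Flips commute with each other and conjugate the rotation: with an
        # xy-flip present the element is its own inverse (dihedral identity
        # F R^k F = R^-k); otherwise invert the rotation.
        if self.flip_xy:
            return self
        inv_rot = {0: 0, 180: 180, 90: -90, -90: 90}[self.rotation]
        return AugTransform(inv_rot, self.flip_xy, self.flip_z)


AUGMENTATIONS: tuple[AugTransform, ...] = tuple(
    AugTransform(rot, fxy, fz)
    for fz in (False, True)
    for fxy in (False, True)
    for rot in (0, 90, 180, -90)
)
"""All 16 train/test-time transforms: 4 rotations x xy-flip x z-flip."""


def apply_augmentation(
    pair: tuple[np.ndarray, np.ndarray],
    transform: AugTransform,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the identical spatial transform to an image patch and its labels.

    Labels are never interpolated — rotations/flips are index permutations.
    With a non-square xy extent and a ±90° rotation the y/x axes swap in the
    output shape (documented behaviour, not an error).
    """
    img, lab = pair
    return transform.apply(img), transform.apply(lab)
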