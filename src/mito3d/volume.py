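"""Core containers for volumetric EM data.

All 3D arrays in this package are indexed ``(z, y, x)``, 0-based: axis 0 walks
through serial sections, axes 1–2 are the imaging plane. Physical voxel edge
lengths are carried alongside the data in nanometres so that morphometric
quantities can be reported in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VoxelSpacing", "Volume", "LabelVolume"]


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel edge lengths in nanometres, ordered (z, y, x).

    ATUM-SEM stacks are strongly anisotropic (fine in-plane sampling, coarse
    section thickness, e.g. 50 x 2 x 2 nm), FIB-SEM volumes are isotropic
    (e.g. 5 x 5 x 5 nm).
    """

    sz: float
    sy: float
    sx: float

    def __post_init__(self) -> None:
        if not (self.sz > 0 and self.sy > 0 and self.sx > 0):
            raise ValueError(f"voxel spacing must be positive, got {self}")

    @property
    def anisotropic(self) -> bool:
        return not (self.sz == self.sx and self.sz == self.sy)

    @property
    def voxel_volume_nm3(self) -> float:
        return self.sz * self.sy * self.sx

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sz, self.sy, self.sx)


#: Table-1 style presets: anisotropic serial-section and isotropic milled volumes.
ATUM_SPACING = VoxelSpacing(50.0, 2.0, 2.0)
FIBSEM_SPACING = VoxelSpacing(5.0, 5.0, 5.0)


def _check_3d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) array, got shape {data.shape}")
    if min(data.shape) < 1:
        raise ValueError(f"all dimensions must be >= 1, got shape {data.shape}")
    return data


@dataclass
class Volume:
    """A 3D grayscale intensity stack with attached voxel spacing."""

    data: np.ndarray
    spacing: VoxelSpacing = field(default=FIBSEM_SPACING)

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def dtype(self) -> np.dtype:
        return self.data.dtype

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same spacing, new voxel data (spacing survives every transform)."""
        return replace(self, data=_check_3d(data))


@dataclass
class LabelVolume:
    """A 3D integer label stack paired with a :class:`Volume`.

    ``binary`` semantics restrict values to {0, 1}; ``instance`` semantics use
    0 for background and k >= 1 as per-mitochondrion identifiers.
    """

    data: np.ndarray
    spacing: VoxelSpacing = field(default=FIBSEM_SPACING)
    semantics: str = "binary"

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label data must be integer-typed, got {self.data.dtype}")
        if self.semantics not in ("binary", "instance"):
            raise ValueError(f"unknown label semantics {self.semantics!r}")
        if self.data.min() < 0:
            raise ValueError("label values must be >= 0")
        if self.semantics == "binary" and self.data.max() > 1:
            raise ValueError("binary labels may only contain {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return replace(self, data=np.asarray(data))

    def instance_sizes(self) -> dict[int, int]:
        """Voxel count per positive label id."""
        counts = np.bincount(self.data.ravel())
        return {int(i): int(c) for i, c in enumerate(counts) if i > 0 and c > 0}
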