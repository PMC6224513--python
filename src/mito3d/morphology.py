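"""Per-mitochondrion 3D morphometry and population summaries.

Each instance is measured in physical units through the voxel spacing:
volume (voxel count x voxel volume, μm³), surface area (triangulated
isosurface of the instance mask at the 0.5 level with spacing applied, μm²
— face counting on the voxel grid would overestimate curved organelles),
length and width (extents of the spacing-scaled voxel cloud along its first
two principal axes, μm), and flatness √(λ₃/λ₂) — the ratio of the third to
second principal standard deviations, close to 0 for pancake-like objects
and 1 for tubes of circular cross-section and spheres. Population summaries
report instance count, number density (N/μm³ of analyzed tissue) and
mean ± sd of each measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import marching_cubes, mesh_surface_area

from .volume import LabelVolume, VoxelSpacing

__all__ = [
    "MorphRecord",
    "MorphSummary",
    "instance_volume",
    "instance_surface_area",
    "instance_axes",
    "measure_instances",
    "summarize",
]

_NM3_TO_UM3 = 1e-9
_NM2_TO_UM2 = 1e-6
_NM_TO_UM = 1e-3


@dataclass(frozen=True)
class MorphRecord:
    """One row of per-instance morphometry (all physical units)."""

    instance_id: int
    volume_um3: float
    surface_um2: float
    surface_to_volume: float  # 1/μm
    length_um: float
    width_um: float
    length_width_ratio: float
    flatness: float
    degenerate: bool = False  # too few / coplanar voxels for full axes


@dataclass(frozen=True)
class MorphSummary:
    count: int
    density_per_um3: float
    total_volume_um3: float
    means: dict[str, float]
    stds: dict[str, float]


def _instance_mask(instances: LabelVolume, instance_id: int) -> np.ndarray:
    mask = instances.data == instance_id
    if not mask.any():
        raise ValueError(f"instance {instance_id} has no voxels")
    return mask


def instance_volume(mask: np.ndarray, spacing: VoxelSpacing) -> float:
    """Voxel count times physical voxel volume, in μm³."""
    n = int(np.asarray(mask, dtype=bool).sum())
    if n == 0:
        raise ValueError("empty instance")
    return n * spacing.voxel_volume_nm3 * _NM3_TO_UM3


def instance_surface_area(mask: np.ndarray, spacing: VoxelSpacing) -> float:
    """Area of the spacing-scaled 0.5-level isosurface mesh, in μm².

    Degenerate instances too thin for a closed isosurface (e.g. a single
    voxel) fall back to the surface of their scaled bounding box.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty instance")
    # a raw 0/1 mask yields a blocky staircase isosurface that overestimates
    # curved areas by ~9%, while heavy smoothing rounds off genuinely sharp
    # corners; sigma = 0.5 voxel keeps both biases below ~5%
    from scipy.ndimage import gaussian_filter

    padded = gaussian_filter(np.pad(mask, 4).astype(np.float64), sigma=0.5)
    try:
        if padded.max() <= 0.5:  # instance too small to survive smoothing
            raise ValueError("no isosurface")
        verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing.as_tuple())
        area_nm2 = mesh_surface_area(verts, faces)
    except (ValueError, RuntimeError):
        zi, yi, xi = np.nonzero(mask)
        ez = (np.ptp(zi) + 1) * spacing.sz
        ey = (np.ptp(yi) + 1) * spacing.sy
        ex = (np.ptp(xi) + 1) * spacing.sx
        area_nm2 = 2.0 * (ez * ey + ez * ex + ey * ex)
    return float(area_nm2 * _NM2_TO_UM2)


def instance_axes(
    mask: np.ndarray,
    spacing: VoxelSpacing,
    flatness_mode: str = "minor_over_middle",
) -> tuple[float, float, float, bool]:
    """(length μm, width μm, flatness, degenerate flag) from principal axes.

    The spacing-scaled voxel-centre cloud is eigen-decomposed; length and
    width are the peak-to-peak extents of the cloud projected on the first
    and second principal axes (plus one mean voxel diameter so a flat or
    single-voxel object keeps a physical thickness). Flatness is √(λ₃/λ₂)
    by default, or √(λ₃/λ₁) with ``flatness_mode='minor_over_major'``.
    """
    if flatness_mode not in ("minor_over_middle", "minor_over_major"):
        raise ValueError(f"unknown flatness mode {flatness_mode!r}")
    mask = np.asarray(mask, dtype=bool)
    coords_vox = np.argwhere(mask)
    if coords_vox.shape[0] == 0:
        raise ValueError("empty instance")
    scale = np.array(spacing.as_tuple()) * _NM_TO_UM
    coords = (coords_vox + 0.5) * scale

    degenerate = coords.shape[0] < 4
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / max(coords.shape[0] - 1, 1)
    # each voxel is a box, not a point: add its uniform variance so one-voxel-
    # thick objects keep a strictly positive minor axis (flatness in (0, 1])
    cov += np.diag(scale**2 / 12.0)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals[::-1], 0.0, None)  # λ1 >= λ2 >= λ3
    evecs = evecs[:, ::-1]

    # one mean voxel edge so extents stay positive for thin/degenerate objects
    voxel_pad = float(np.mean(scale))
    proj = centered @ evecs
    length = float(np.ptp(proj[:, 0]) + voxel_pad)
    width = float(np.ptp(proj[:, 1]) + voxel_pad)
    if width > length:  # padding can flip near-isotropic cases
        length, width = width, length

    if evals[1] <= 0:
        degenerate = True
        flatness = 1.0
    else:
        denom = evals[0] if flatness_mode == "minor_over_major" else evals[1]
        flatness = float(np.sqrt(evals[2] / denom))
    return length, width, flatness, degenerate


def measure_instances(
    instances: LabelVolume,
    spacing: VoxelSpacing | None = None,
    flatness_mode: str = "minor_over_middle",
) -> list[MorphRecord]:
    """Morphometry rows for every instance id present in the labeling."""
    spacing = spacing or instances.spacing
    records = []
    for inst_id in sorted(instances.instance_sizes()):
        mask = _instance_mask(instances, inst_id)
        vol = instance_volume(mask, spacing)
        surf = instance_surface_area(mask, spacing)
        length, width, flatness, degenerate = instance_axes(mask, spacing, flatness_mode)
        records.append(
            MorphRecord(
                instance_id=inst_id,
                volume_um3=vol,
                surface_um2=surf,
                surface_to_volume=surf / vol,
                length_um=length,
                width_um=width,
                length_width_ratio=length / width,
                flatness=flatness,
                degenerate=degenerate,
            )
        )
    return records


_SUMMARY_FIELDS = (
    "volume_um3",
    "surface_um2",
    "surface_to_volume",
    "length_um",
    "width_um",
    "length_width_ratio",
    "flatness",
)


def summarize(records: list[MorphRecord], analyzed_volume_um3: float) -> MorphSummary:
    """Count, number density and mean ± sd over all morphometry fields.

    The surface/volume summary is the mean of per-instance ratios (not the
    ratio of means). Densities are instances per μm³ of analyzed tissue.
    """
    if not records:
        raise ValueError("no morphometry records to summarize")
    if analyzed_volume_um3 <= 0:
        raise ValueError("analyzed volume must be positive")
    frame = records_to_frame(records)
    means = {f: float(frame[f].mean()) for f in _SUMMARY_FIELDS}
    stds = {f: float(frame[f].std(ddof=0)) for f in _SUMMARY_FIELDS}
    return MorphSummary(
        count=len(records),
        density_per_um3=len(records) / analyzed_volume_um3,
        total_volume_um3=analyzed_volume_um3,
        means=means,
        stds=stds,
    )


def records_to_frame(records: list[MorphRecord]) -> pd.DataFrame:
    """Morphometry records as a DataFrame (CSV-export ready)."""
    return pd.DataFrame([r.__dict__ for r in records])


def export_instance_meshes(
    instances: LabelVolume,
    out_dir,
    spacing: VoxelSpacing | None = None,
) -> list[str]:
    """Write one Wavefront OBJ isosurface mesh per instance (μm coordinates).

    Replaces interactive 3D visualization: the meshes load into any external
    viewer. Instances too small for an isosurface are skipped. Returns the
    written file paths.
    """
    from pathlib import Path

    from scipy.ndimage import gaussian_filter

    spacing = spacing or instances.spacing
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for inst_id in sorted(instances.instance_sizes()):
        mask = instances.data == inst_id
        padded = gaussian_filter(np.pad(mask, 4).astype(np.float64), sigma=0.5)
        if padded.max() <= 0.5:
            continue
        verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing.as_tuple())
        verts = (verts - 4.0 * np.array(spacing.as_tuple())) * _NM_TO_UM  # unpad, nm->um
        path = out_dir / f"instance_{inst_id:04d}.obj"
        with open(path, "w") as fh:
            fh.write(f"# mito3d instance {inst_id}\n")
            for v in verts:
                fh.write(f"v {v[2]:.6f} {v[1]:.6f} {v[0]:.6f}\n")  # OBJ is x y z
            for f in faces + 1:  # OBJ indices are 1-based
                fh.write(f"f {f[0]} {f[1]} {f[2]}\n")
        written.append(str(path))
    return written
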