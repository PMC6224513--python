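"""IoU-based linking of per-slice 2D components into 3D instances.

The network outputs a binary foreground mask per section; individual
mitochondria are recovered by (1) labeling 2D connected components within
each slice, (2) computing the intersection-over-union of the xy footprints of
every component pair in adjacent slices, (3) linking pairs whose IoU reaches
a threshold T (default 0.1 — links with smaller IoU are discarded as likely
spurious), and (4) taking connected components of the link graph via
union-find. A component may link to several partners, so branching and
merging organelles stay single instances. Detected instances below a minimum
voxel count (default 1,500) can be removed before detection-level evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .volume import LabelVolume

__all__ = [
    "ConnectConfig",
    "slice_components",
    "link_components",
    "filter_small",
    "connect",
]


@dataclass(frozen=True)
class ConnectConfig:
    """Linking threshold, in-plane connectivity and the small-instance filter."""

    iou_threshold: float = 0.1
    connectivity: int = 8  # in-plane: 4 or 8
    min_voxels: int = 1500

    def __post_init__(self) -> None:
        if not (0.0 <= self.iou_threshold <= 1.0):
            raise ValueError(f"IoU threshold must lie in [0, 1], got {self.iou_threshold}")
        if self.connectivity not in (4, 8):
            raise ValueError("in-plane connectivity must be 4 or 8")
        if self.min_voxels < 0:
            raise ValueError("min_voxels must be >= 0")


def slice_components(mask: LabelVolume | np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label 2D connected components independently in every z-slice.

    Returns an integer stack where each slice holds its own 1..n_z labeling
    (0 = background). Label order is deterministic (row-major first pixel).
    """
    data = mask.data if isinstance(mask, LabelVolume) else np.asarray(mask)
    if not np.isin(np.unique(data), [0, 1]).all():
        raise ValueError("slice_components expects a binary mask")
    conn = 1 if connectivity == 4 else 2
    out = np.zeros(data.shape, dtype=np.int32)
    for z in range(data.shape[0]):
        out[z] = cc_label(data[z], connectivity=conn)
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:  # path compression
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _adjacent_overlaps(sl_a: np.ndarray, sl_b: np.ndarray):
    """Pairs of component labels with positive footprint overlap, plus sizes."""
    both = (sl_a > 0) & (sl_b > 0)
    if not both.any():
        return {}
    pairs = np.stack([sl_a[both], sl_b[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(uniq, counts)}


def link_components(
    slice_labels: np.ndarray,
    iou_threshold: float = 0.1,
) -> LabelVolume:
    """Union components across adjacent slices whose footprint IoU >= T.

    For components A (slice z) and B (slice z+1), IoU = |A∩B| / |A∪B| over
    their xy footprints. A link is created iff IoU >= T; one component may
    link to multiple partners. Instances are the connected components of the
    link graph. Resulting ids are contiguous, ordered by first voxel in
    (z, y, x) scan order.
    """
    nz = slice_labels.shape[0]
    # global node index per (slice, local label)
    offsets = np.zeros(nz + 1, dtype=np.int64)
    for z in range(nz):
        offsets[z + 1] = offsets[z] + int(slice_labels[z].max())
    n_nodes = int(offsets[-1])
    uf = _UnionFind(n_nodes)

    sizes = [np.bincount(slice_labels[z].ravel()) for z in range(nz)]
    for z in range(nz - 1):
        overlaps = _adjacent_overlaps(slice_labels[z], slice_labels[z + 1])
        for (a, b), inter in overlaps.items():
            union = sizes[z][a] + sizes[z + 1][b] - inter
            if inter / union >= iou_threshold:
                uf.union(int(offsets[z] + a - 1), int(offsets[z + 1] + b - 1))

    # relabel: map every slice-component to its union-find root, then compact
    root_of = np.array([uf.find(i) for i in range(n_nodes)], dtype=np.int64)
    out = np.zeros(slice_labels.shape, dtype=np.int32)
    for z in range(nz):
        sl = slice_labels[z]
        fg = sl > 0
        if fg.any():
            out[z][fg] = root_of[offsets[z] + sl[fg] - 1] + 1
    # compact ids in first-voxel scan order
    flat = out.ravel()
    seen, first_pos = np.unique(flat[flat > 0], return_index=True)
    order = np.argsort(first_pos)
    remap = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    for new_id, old in enumerate(seen[order], start=1):
        remap[old] = new_id
    out = remap[out]
    return LabelVolume(out.astype(np.int32), semantics="instance")


def filter_small(instances: LabelVolume, min_voxels: int) -> LabelVolume:
    """Remove instances with fewer than ``min_voxels`` voxels; compact ids."""
    data = instances.data
    counts = np.bincount(data.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=data.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return LabelVolume(remap[data], instances.spacing, semantics="instance")


def connect(
    mask: LabelVolume | np.ndarray,
    config: ConnectConfig | None = None,
    apply_min_filter: bool = False,
) -> LabelVolume:
    """Full 3D connection: slice components -> IoU linking -> optional filter.

    The minimum-size filter is off by default; it belongs to detection-level
    evaluation rather than to pixel-level scoring.
    """
    config = config or ConnectConfig()
    spacing = mask.spacing if isinstance(mask, LabelVolume) else None
    slice_labels = slice_components(mask, config.connectivity)
    instances = link_components(slice_labels, config.iou_threshold)
    if spacing is not None:
        instances = LabelVolume(instances.data, spacing, semantics="instance")
    if apply_min_filter and config.min_voxels > 0:
        instances = filter_small(instances, config.min_voxels)
    return instances
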