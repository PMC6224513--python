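"""Whole-volume prediction: overlapping tiles, blending, test-time augmentation.

Same-padded convolutions degrade near patch edges, so whole volumes are
predicted on overlapping tiles whose probability maps are blended by plain
unweighted averaging. Tiles are placed on a uniform grid with stride
``tile - overlap``; the final tile per axis is shifted flush with the volume
boundary so every voxel is covered. The published regimes (1152 x 1152 x 8
tiles with 256/5-voxel overlaps for anisotropic stacks; 448 x 576 x 20 with
128/10 for isotropic) are plain :class:`TileSpec` values here.

Test-time augmentation predicts on symmetry-transformed copies of the volume
(16 = full rotation/flip group, 8 = the subgroup without z-flips, 1 =
identity), inverse-transforms each probability map and averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io_preprocess import AUGMENTATIONS, AugTransform
from .network import SegmentationModel, forward
from .volume import LabelVolume, Volume

__all__ = [
    "TileSpec",
    "predict_volume",
    "tta_predict",
    "binarize",
    "ATUM_TILES",
    "FIBSEM_TILES",
]


@dataclass(frozen=True)
class TileSpec:
    """Tile shape and overlap in voxels, (z, y, x)."""

    shape: tuple[int, int, int]
    overlap: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError(f"tile shape must be positive, got {self.shape}")
        if any(not (0 <= o < s) for o, s in zip(self.overlap, self.shape)):
            raise ValueError(
                f"overlap must satisfy 0 <= overlap < tile per axis, "
                f"got {self.overlap} for tile {self.shape}"
            )

    def fitted_to(self, shape: tuple[int, int, int]) -> "TileSpec":
        """Shrink the tile to the volume where the volume is smaller."""
        if all(t <= d for t, d in zip(self.shape, shape)):
            return self
        new_shape = tuple(min(t, d) for t, d in zip(self.shape, shape))
        new_overlap = tuple(min(o, s - 1) for o, s in zip(self.overlap, new_shape))
        warnings.warn(
            f"tile {self.shape} exceeds volume {shape}; shrinking to {new_shape}",
            stacklevel=3,
        )
        return TileSpec(new_shape, new_overlap)


#: Published inference regimes, (z, y, x).
ATUM_TILES = TileSpec(shape=(8, 1152, 1152), overlap=(5, 256, 256))
FIBSEM_TILES = TileSpec(shape=(20, 448, 576), overlap=(10, 128, 128))


def _axis_starts(dim: int, tile: int, overlap: int) -> list[int]:
    stride = tile - overlap
    starts = list(range(0, dim - tile + 1, stride))
    if starts[-1] + tile < dim:
        starts.append(dim - tile)
    return starts


def tile_origins(shape: tuple[int, int, int], spec: TileSpec) -> list[tuple[int, int, int]]:
    """Deterministic tile corner list covering every voxel at least once."""
    zs = _axis_starts(shape[0], spec.shape[0], spec.overlap[0])
    ys = _axis_starts(shape[1], spec.shape[1], spec.overlap[1])
    xs = _axis_starts(shape[2], spec.shape[2], spec.overlap[2])
    return [(z, y, x) for z in zs for y in ys for x in xs]


PredictFn = Callable[[np.ndarray], np.ndarray]


def _model_predictor(model: SegmentationModel | PredictFn, intensity_scale: float) -> PredictFn:
    if callable(model) and not isinstance(model, SegmentationModel):
        return model

    def predict(patch: np.ndarray) -> np.ndarray:
        probs = forward(model, patch.astype(np.float64) / intensity_scale, mode="infer")
        return probs[1]  # foreground class

    return predict


def predict_volume(
    model: SegmentationModel | PredictFn,
    volume: Volume,
    tile_spec: TileSpec,
    intensity_scale: float = 255.0,
) -> Volume:
    """Foreground probability map for a whole volume by tiled blending.

    ``model`` is either a trained :class:`SegmentationModel` or any callable
    mapping a (z, y, x) patch to a same-shape probability patch. Overlapping
    tile predictions are averaged voxel-wise; the output is a float map in
    [0, 1] with the input's shape and spacing.
    """
    spec = tile_spec.fitted_to(volume.shape)
    predictor = _model_predictor(model, intensity_scale)
    tz, ty, tx = spec.shape
    acc = np.zeros(volume.shape, dtype=np.float64)
    cover = np.zeros(volume.shape, dtype=np.int32)
    for z, y, x in tile_origins(volume.shape, spec):
        patch = volume.data[z : z + tz, y : y + ty, x : x + tx]
        pred = predictor(np.asarray(patch))
        if pred.shape != patch.shape:
            raise ValueError(
                f"predictor returned shape {pred.shape} for tile of shape {patch.shape}"
            )
        acc[z : z + tz, y : y + ty, x : x + tx] += pred
        cover[z : z + tz, y : y + ty, x : x + tx] += 1
    assert cover.min() >= 1
    return Volume(acc / cover, volume.spacing)


def _tta_group(variants: int) -> tuple[AugTransform, ...]:
    if variants == 1:
        return (AugTransform(),)
    if variants == 8:
        return tuple(t for t in AUGMENTATIONS if not t.flip_z)
    if variants == 16:
        return AUGMENTATIONS
    raise ValueError(f"variants must be 1, 8 or 16, got {variants}")


def tta_predict(
    model: SegmentationModel | PredictFn,
    volume: Volume,
    tile_spec: TileSpec,
    variants: int = 16,
    intensity_scale: float = 255.0,
) -> Volume:
    """Test-time-augmented prediction averaged over a transform subgroup.

    Each variant transforms the volume, predicts by tiled blending, applies
    the inverse transform to the probability map, and the final map is the
    arithmetic mean. ±90° rotations of non-square volumes simply swap the
    y/x axes (the tile spec is swapped accordingly); no padding is needed.
    """
    group = _tta_group(variants)
    acc = np.zeros(volume.shape, dtype=np.float64)
    for t in group:
        tvol = Volume(t.apply(volume.data), volume.spacing)
        spec = tile_spec
        if t.rotation in (90, -90):
            tz, ty, tx = tile_spec.shape
            oz, oy, ox = tile_spec.overlap
            spec = TileSpec((tz, tx, ty), (oz, ox, oy))
        prob = predict_volume(model, tvol, spec, intensity_scale=intensity_scale)
        acc += t.inverse().apply(prob.data)
    return Volume(acc / len(group), volume.spacing)


def binarize(prob_map: Volume, threshold: float = 0.5) -> LabelVolume:
    """Threshold a probability map: voxel = 1 iff p >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    data = np.asarray(prob_map.data)
    if data.min() < 0 or data.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = (data >= threshold).astype(np.uint8)
    return LabelVolume(mask, prob_map.spacing, semantics="binary")
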