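"""Deeply supervised 3D residual fully convolutional segmentation network.

An asymmetric U-Net variant for volumetric EM data: a contracting path of
1 input convolution + 6 two-conv residual blocks (13 convolutions) and an
expansive path of 6 residual blocks + 2 transition convolutions + 1 main
classifier (15 convolutions). Every 3x3x3 convolution is followed by batch
normalisation and ELU; residual shortcuts are identities (zero-padded along
channels where the width grows). Pooling/upsampling use a 2x2x1 in-plane
stride by default, preserving the z-resolution of anisotropic serial-section
stacks; an isotropic preset switches the two coarsest transitions to 2x2x2.
Encoder and decoder features meet through summation-based skip connections.

Deep supervision attaches auxiliary softmax classifiers to the two coarsest
decoder stages via nearest-neighbour upsampling to full resolution; their
cross-entropy losses join the main loss with discount weights (0.15 for the
deeper head, 0.30 for the shallower) plus an L2 term:

    L = CE(main) + sum_c w_c * CE(aux_c) + (lambda/2) (||W||^2 + sum ||W_c||^2)

with CE the mean-over-voxels negative log-likelihood of the softmax output.
At inference the auxiliary heads are discarded.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from ._nn import Parameter, Tensor

__all__ = [
    "NetworkConfig",
    "SegmentationModel",
    "build_model",
    "forward",
    "deep_supervision_loss",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and loss hyperparameters.

    ``widths`` are trunk channel counts per resolution level (defaults chosen
    so the full model carries about 1.1 M trainable parameters);
    ``pool_strides`` are the (z, y, x) pooling/upsampling strides between
    consecutive levels. ``aux_levels`` index decoder stages from the deepest
    (0) upward; ``aux_weights`` are the matching discount weights.
    ``lambda_reg`` is the L2 balance weight (not stated with the published
    training setup; 1e-4 is this package's default).
    """

    in_channels: int = 1
    widths: tuple[int, ...] = (10, 20, 40, 80)
    encoder_blocks: tuple[int, ...] = (1, 1, 2, 2)
    decoder_blocks: int = 2
    pool_strides: tuple[tuple[int, int, int], ...] = ((1, 2, 2), (1, 2, 2), (1, 2, 2))
    aux_levels: tuple[int, ...] = (0, 1)
    aux_weights: tuple[float, ...] = (0.15, 0.3)
    lambda_reg: float = 1e-4
    num_classes: int = 2

    def __post_init__(self) -> None:
        L = len(self.widths)
        if L < 2:
            raise ValueError("need at least two resolution levels")
        if len(self.encoder_blocks) != L:
            raise ValueError("encoder_blocks must list one count per level")
        if len(self.pool_strides) != L - 1:
            raise ValueError("pool_strides must list one stride per level transition")
        if len(self.aux_levels) != len(self.aux_weights):
            raise ValueError("aux_levels and aux_weights must have equal length")
        n_stages = L - 1
        if any(not (0 <= a < n_stages) for a in self.aux_levels):
            raise ValueError(f"aux_levels must index decoder stages 0..{n_stages - 1}")
        if any(not (0.0 <= w <= 1.0) for w in self.aux_weights):
            raise ValueError("aux weights must lie in [0, 1]")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")

    @classmethod
    def isotropic(cls, **overrides) -> "NetworkConfig":
        """Preset for isotropic volumes: 2x2x2 strides at the two coarsest levels."""
        widths = overrides.pop("widths", cls.widths)
        L = len(widths)
        strides = [(1, 2, 2)] * (L - 1)
        for i in range(max(0, L - 3), L - 1):
            strides[i] = (2, 2, 2)
        return cls(widths=widths, pool_strides=tuple(strides), **overrides)

    @classmethod
    def tiny(cls, base: int = 8) -> "NetworkConfig":
        """Two-level desk-scale model for experiments and tests."""
        return cls(
            widths=(base, 2 * base),
            encoder_blocks=(1, 1),
            pool_strides=((1, 2, 2),),
            aux_levels=(0,),
            aux_weights=(0.3,),
        )

    @property
    def levels(self) -> int:
        return len(self.widths)

    def cumulative_strides(self) -> tuple[int, int, int]:
        cz = cy = cx = 1
        for sz, sy, sx in self.pool_strides:
            cz *= sz
            cy *= sy
            cx *= sx
        return cz, cy, cx


def _he_conv(rng: np.ndarray, cout: int, cin: int, k: tuple[int, int, int]) -> Parameter:
    fan_in = cin * k[0] * k[1] * k[2]
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin) + k)
    return Parameter(w)


class _ConvBNAct:
    """3D convolution -> BN -> ELU (activation optional)."""

    def __init__(self, rng, cin: int, cout: int, kernel=(3, 3, 3), act: bool = True) -> None:
        self.w = _he_conv(rng, cout, cin, kernel)
        self.b = Parameter(np.zeros(cout))
        self.bn = _nn.BatchNorm3d(cout)
        self.act = act

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        out = self.bn(_nn.conv3d(x, self.w, self.b), train)
        return _nn.elu(out) if self.act else out

    @property
    def parameters(self) -> list[Parameter]:
        return [self.w, self.b] + self.bn.parameters


class _ResBlock:
    """Two 3x3x3 convolutions with an identity shortcut.

    When the block widens the channel count the shortcut is the input
    zero-padded along channels (parameter-free), keeping the convolution
    census unchanged. Activation after the addition.
    """

    def __init__(self, rng, cin: int, cout: int) -> None:
        self.conv1 = _ConvBNAct(rng, cin, cout)
        self.conv2 = _ConvBNAct(rng, cout, cout, act=False)
        self.cin, self.cout = cin, cout

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        h = self.conv2(self.conv1(x, train), train)
        shortcut = x if self.cin == self.cout else _nn.channel_pad(x, self.cout)
        return _nn.elu(_nn.add(h, shortcut))

    @property
    def parameters(self) -> list[Parameter]:
        return self.conv1.parameters + self.conv2.parameters

    n_convs = 2


class _Classifier:
    """1x1x1 softmax classifier head."""

    def __init__(self, rng, cin: int, n_classes: int) -> None:
        self.w = _he_conv(rng, n_classes, cin, (1, 1, 1))
        self.b = Parameter(np.zeros(n_classes))

    def __call__(self, x: Tensor) -> Tensor:
        return _nn.conv3d(x, self.w, self.b)

    @property
    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]


class SegmentationModel:
    """Parameter store plus forward graph for the residual 3D FCN."""

    def __init__(self, config: NetworkConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        W = config.widths
        L = config.levels

        self.stem = _ConvBNAct(rng, config.in_channels, W[0])
        self.encoder: list[list[_ResBlock]] = []
        for lvl in range(L):
            blocks = []
            cin = W[lvl - 1] if lvl > 0 else W[0]
            for bi in range(config.encoder_blocks[lvl]):
                blocks.append(_ResBlock(rng, cin if bi == 0 else W[lvl], W[lvl]))
            self.encoder.append(blocks)

        # decoder stages run deepest -> shallowest; the two deepest get a
        # transition convolution after upsampling, the shallowest reduces
        # channels by slicing so the expansive census stays at 15.
        self.dec_transitions: list[_ConvBNAct | None] = []
        self.decoder: list[list[_ResBlock]] = []
        n_stages = L - 1
        for stage in range(n_stages):
            lvl = L - 2 - stage  # target level of this stage
            last_stage = stage == n_stages - 1
            if last_stage:
                self.dec_transitions.append(None)
            else:
                self.dec_transitions.append(_ConvBNAct(rng, W[lvl + 1], W[lvl]))
            self.decoder.append(
                [_ResBlock(rng, W[lvl], W[lvl]) for _ in range(config.decoder_blocks)]
            )

        self.classifier = _Classifier(rng, W[0], config.num_classes)
        self.aux_classifiers = [
            _Classifier(rng, W[L - 2 - stage], config.num_classes)
            for stage in config.aux_levels
        ]

    # -- parameter bookkeeping ------------------------------------------------

    def main_parameters(self) -> list[Parameter]:
        """W: trunk + main classifier parameters."""
        params = list(self.stem.parameters)
        for blocks in self.encoder:
            for b in blocks:
                params += b.parameters
        for t in self.dec_transitions:
            if t is not None:
                params += t.parameters
        for blocks in self.decoder:
            for b in blocks:
                params += b.parameters
        params += self.classifier.parameters
        return params

    def aux_parameters(self) -> list[Parameter]:
        """W_c: auxiliary classifier parameters."""
        params: list[Parameter] = []
        for c in self.aux_classifiers:
            params += c.parameters
        return params

    def parameters(self) -> list[Parameter]:
        return self.main_parameters() + self.aux_parameters()

    def layer_census(self) -> tuple[int, int]:
        """(contracting, expansive) convolution counts of the main path."""
        contracting = 1 + sum(b.n_convs for blocks in self.encoder for b in blocks)
        expansive = (
            sum(b.n_convs for blocks in self.decoder for b in blocks)
            + sum(1 for t in self.dec_transitions if t is not None)
            + 1  # main classifier
        )
        return contracting, expansive

    def batchnorms(self) -> list[_nn.BatchNorm3d]:
        bns = [self.stem.bn]
        for blocks in self.encoder:
            for b in blocks:
                bns += [b.conv1.bn, b.conv2.bn]
        for t in self.dec_transitions:
            if t is not None:
                bns.append(t.bn)
        for blocks in self.decoder:
            for b in blocks:
                bns += [b.conv1.bn, b.conv2.bn]
        return bns

    # -- forward graph --------------------------------------------------------

    def _check_shape(self, shape: tuple[int, int, int]) -> None:
        cz, cy, cx = self.config.cumulative_strides()
        for name, dim, c in (("z", shape[0], cz), ("y", shape[1], cy), ("x", shape[2], cx)):
            if dim % c != 0:
                raise ValueError(
                    f"input axis {name} extent {dim} is not divisible by the "
                    f"cumulative pooling stride {c}"
                )

    def forward_tensors(self, x: Tensor, train: bool) -> tuple[Tensor, list[Tensor]]:
        """Main logits and (in train mode) auxiliary logits, full resolution."""
        cfg = self.config
        self._check_shape(x.data.shape[2:])
        h = self.stem(x, train)
        skips: list[Tensor] = []
        for lvl, blocks in enumerate(self.encoder):
            for b in blocks:
                h = b(h, train)
            if lvl < cfg.levels - 1:
                skips.append(h)
                h = _nn.maxpool3d(h, cfg.pool_strides[lvl])

        aux_logits: list[Tensor] = []
        n_stages = cfg.levels - 1
        for stage in range(n_stages):
            lvl = cfg.levels - 2 - stage
            h = _nn.upsample_nearest(h, cfg.pool_strides[lvl])
            trans = self.dec_transitions[stage]
            if trans is not None:
                h = trans(h, train)
            else:
                h = _nn.channel_slice(h, cfg.widths[lvl])
            h = _nn.add(h, skips[lvl])
            for b in self.decoder[stage]:
                h = b(h, train)
            if train and stage in cfg.aux_levels:
                head = self.aux_classifiers[cfg.aux_levels.index(stage)]
                up = h
                fz = fy = fx = 1
                for s in cfg.pool_strides[:lvl]:
                    fz *= s[0]
                    fy *= s[1]
                    fx *= s[2]
                if (fz, fy, fx) != (1, 1, 1):
                    up = _nn.upsample_nearest(up, (fz, fy, fx))
                aux_logits.append(head(up))

        return self.classifier(h), aux_logits


def build_model(config: NetworkConfig | None = None, seed: int = 0) -> SegmentationModel:
    """Construct the network with freshly initialised parameters."""
    return SegmentationModel(config or NetworkConfig(), seed=seed)


def count_parameters(model: SegmentationModel) -> int:
    """Total trainable scalars in the trunk, main and auxiliary classifiers."""
    return sum(p.size for p in model.parameters())


def _prepare_input(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim == 3:
        patch = patch[None, None]
    elif patch.ndim == 4:
        patch = patch[:, None]
    elif patch.ndim != 5:
        raise ValueError(f"expected (z,y,x) or batched patch, got shape {patch.shape}")
    return patch


def forward(
    model: SegmentationModel,
    patch: np.ndarray,
    mode: str = "infer",
) -> np.ndarray | tuple[np.ndarray, list[np.ndarray]]:
    """Run the network on one patch.

    Returns per-class softmax probabilities of shape (C, Z, Y, X) matching the
    input spatial extent. In ``train`` mode the auxiliary probability maps
    (also full resolution) are returned as well; in ``infer`` mode the
    auxiliary heads are discarded.
    """
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    x = Tensor(_prepare_input(patch))
    main, auxes = model.forward_tensors(x, train=(mode == "train"))
    main_p = _nn.softmax(main.data)[0]
    if mode == "infer":
        return main_p
    return main_p, [_nn.softmax(a.data)[0] for a in auxes]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _cross_entropy_from_probs(prob_map: np.ndarray, labels: np.ndarray) -> float:
    """Mean-over-voxels NLL over the foreground and background label sets."""
    prob_map = np.asarray(prob_map, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label volume")
    uniq = np.unique(labels)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError(f"labels must be binary, found values {uniq}")
    if prob_map.ndim == labels.ndim:  # foreground probability
        p_fg = prob_map
    elif prob_map.ndim == labels.ndim + 1:  # class axis first
        p_fg = prob_map[1]
    else:
        raise ValueError(
            f"probability map shape {prob_map.shape} incompatible with labels {labels.shape}"
        )
    if p_fg.shape != labels.shape:
        raise ValueError(
            f"probability map shape {p_fg.shape} incompatible with labels {labels.shape}"
        )
    p = np.where(labels == 1, p_fg, 1.0 - p_fg)
    return float(-np.log(np.clip(p, 1e-300, None)).mean())


def deep_supervision_loss(
    main_map: np.ndarray,
    aux_maps: list[np.ndarray] | tuple[np.ndarray, ...],
    labels: np.ndarray,
    config: NetworkConfig,
    model: SegmentationModel | None = None,
) -> float:
    """Total training objective evaluated on probability maps.

    CE(main) + sum_c w_c * CE(aux_c) + (lambda/2)(||W||^2 + sum_c ||W_c||^2),
    with cross-entropy reduced as the mean over voxels. The L2 term requires
    the model's parameters; when ``model`` is omitted only the data terms are
    returned.
    """
    if len(aux_maps) > len(config.aux_weights):
        raise ValueError(
            f"{len(aux_maps)} auxiliary maps but only {len(config.aux_weights)} weights"
        )
    total = _cross_entropy_from_probs(main_map, labels)
    for w, amap in zip(config.aux_weights, aux_maps):
        total += w * _cross_entropy_from_probs(amap, labels)
    if model is not None and config.lambda_reg > 0:
        sq = sum(float((p.data**2).sum()) for p in model.parameters())
        total += 0.5 * config.lambda_reg * sq
    return total


def training_loss_tensors(
    model: SegmentationModel,
    main_logits: Tensor,
    aux_logits: list[Tensor],
    labels: np.ndarray,
) -> Tensor:
    """Differentiable version of the objective, built on the logits tape."""
    cfg = model.config
    terms = [_nn.softmax_cross_entropy(main_logits, labels)]
    for w, logit in zip(cfg.aux_weights, aux_logits):
        terms.append(_nn.scale(_nn.softmax_cross_entropy(logit, labels), w))
    if cfg.lambda_reg > 0:
        terms.append(_nn.scale(_nn.sum_squares(model.parameters()), 0.5 * cfg.lambda_reg))
    return _nn.add_scalars(terms)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path) -> None:
    """Single-file archive: parameters + running BN stats + JSON config."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    for i, bn in enumerate(model.batchnorms()):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    cfg = json.dumps(asdict(model.config))
    arrays["config_json"] = np.frombuffer(cfg.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _config_from_dict(d: dict) -> NetworkConfig:
    def tt(v):
        return tuple(tuple(i) if isinstance(i, list) else i for i in v)

    return NetworkConfig(
        in_channels=d["in_channels"],
        widths=tuple(d["widths"]),
        encoder_blocks=tuple(d["encoder_blocks"]),
        decoder_blocks=d["decoder_blocks"],
        pool_strides=tt(d["pool_strides"]),
        aux_levels=tuple(d["aux_levels"]),
        aux_weights=tuple(d["aux_weights"]),
        lambda_reg=d["lambda_reg"],
        num_classes=d["num_classes"],
    )


def load_checkpoint(path) -> SegmentationModel:
    with np.load(path) as archive:
        cfg = _config_from_dict(json.loads(bytes(archive["config_json"]).decode()))
        model = SegmentationModel(cfg, seed=0)
        for i, p in enumerate(model.parameters()):
            p.data = archive[f"p{i}"].astype(np.float64)
        for i, bn in enumerate(model.batchnorms()):
            bn.running_mean = archive[f"bn{i}_mean"].astype(np.float64)
            bn.running_var = archive[f"bn{i}_var"].astype(np.float64)
    return model
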