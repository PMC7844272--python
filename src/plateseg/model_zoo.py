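"""Hybrid 2D-3D segmentation networks and ablations.

The flagship architecture composes a 2D U-Net-style encoder-decoder with a 3D
convolutional spatial pyramid.  The "2D" module operates on a 3D window but
uses only 1x3x3 convolutions and 1x2x2 pooling / transposed convolutions, so
each z-slice is processed independently within one computation graph; optional
3x3x3 convolutions at the beginning of the first two encoder blocks and the
last two decoder blocks mix information across z.  All convolutions are
zero-padded shape-preserving, use bias terms, and are followed by ReLU.

The 2D module emits ``feature_width_out`` features per voxel, from which a
1x1x1 predictor convolution plus per-voxel softmax forms intermediate 2D
class predictions ``xhat_2d``.  Features and ``xhat_2d`` are concatenated and
fed to the 3D pyramid: scale 0 processes the input directly, scale 1 the
1x2x2 max-pooled input; each scale passes through its own 3x3x3 convolution
block, and the scale-1 output is nearest-neighbour upsampled and added
residually to the scale-0 output.  A final 1x1x1 predictor plus softmax forms
the 3D class predictions ``xhat_3d``, whose voxelwise argmax is the network's
segmentation.  Both heads are centre-cropped by a fixed spatial margin
(default 2 voxels per lateral side, mapping (5, 300, 300) inputs to
(5, 296, 296) predictions).

Ablation toggles:

* ``use_333_convs=False`` -- the block-initial 3x3x3 convolutions become
  otherwise-identical 1x3x3 convolutions.
* ``use_multi_loss=False`` -- architecture unchanged; the training loss drops
  the ``xhat_2d`` term.
* ``use_3d_pyramid=False`` -- no pyramid and no 3D head; ``xhat_2d`` is the
  network output.

Channel widths and block counts are configurable; the defaults (encoder
channels 64/128/256, two same-scale convolutions per block plus the optional
block-initial 3x3x3, mirrored decoder, 64 output features) satisfy the
architectural constraints above.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .nn import autograd as ag
from .volume_io import N_CLASSES

K2D = (1, 3, 3)
K3D = (3, 3, 3)
K1 = (1, 1, 1)


@dataclass
class ModelConfig:
    use_333_convs: bool = True
    use_3d_pyramid: bool = True
    use_multi_loss: bool = True
    encoder_channels: tuple[int, ...] = (64, 128, 256)
    convs_per_block: int = 2
    feature_width_out: int = 64
    pyramid_channels: int = 64
    pyramid_convs_per_block: int = 2
    n_classes: int = N_CLASSES
    crop_margin: tuple[int, int, int] = (0, 2, 2)
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError("the labeling schema fixes n_classes = 7")
        if len(self.encoder_channels) < 2:
            raise ValueError("encoder needs at least 2 blocks")
        if self.feature_width_out < self.n_classes:
            raise ValueError("feature_width_out must be >= n_classes")
        if self.convs_per_block < 1 or self.pyramid_convs_per_block < 1:
            raise ValueError("blocks need at least one convolution")


@dataclass
class NetworkParams:
    """Exhaustive disjoint partition of the trainable variables."""

    theta_2d: list[nn.Parameter] = field(default_factory=list)
    theta_3d: list[nn.Parameter] = field(default_factory=list)
    theta_2dp: list[nn.Parameter] = field(default_factory=list)
    theta_3dp: list[nn.Parameter] = field(default_factory=list)


class HybridNet(nn.Module):
    """The 2D-3D (+ 3x3x3) segmentation network."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        ch = config.encoder_channels
        n_scales = len(ch)
        kb = K3D if config.use_333_convs else K2D

        self.enc_blocks: list[list[nn.Conv3d]] = []
        cin = 1
        for s in range(n_scales):
            block: list[nn.Conv3d] = []
            if s < 2:  # block-initial 3x3x3 (or ablated 1x3x3) conv
                block.append(
                    nn.Conv3d(cin, ch[s], kb, f"enc{s}.init", "theta_2d", rng)
                )
                cin = ch[s]
            for i in range(config.convs_per_block):
                block.append(
                    nn.Conv3d(cin, ch[s], K2D, f"enc{s}.conv{i}", "theta_2d", rng)
                )
                cin = ch[s]
            self.enc_blocks.append(block)

        self.upconvs: list[nn.ConvTranspose] = []
        self.dec_blocks: list[list[nn.Conv3d]] = []
        n_dec = n_scales - 1
        for d, s in enumerate(range(n_scales - 2, -1, -1)):
            self.upconvs.append(
                nn.ConvTranspose(
                    ch[s + 1], ch[s], (1, 2, 2), f"dec{s}.up", "theta_2d", rng
                )
            )
            block = []
            cin = 2 * ch[s]  # concatenated skip connection
            if d >= n_dec - 2:  # last two decoder blocks get the block-initial conv
                block.append(
                    nn.Conv3d(cin, ch[s], kb, f"dec{s}.init", "theta_2d", rng)
                )
                cin = ch[s]
            for i in range(config.convs_per_block):
                block.append(
                    nn.Conv3d(cin, ch[s], K2D, f"dec{s}.conv{i}", "theta_2d", rng)
                )
                cin = ch[s]
            self.dec_blocks.append(block)

        self.feature_conv = None
        if config.feature_width_out != ch[0]:
            self.feature_conv = nn.Conv3d(
                ch[0], config.feature_width_out, K2D, "features", "theta_2d", rng
            )
        self.pred_2d = nn.Conv3d(
            config.feature_width_out, config.n_classes, K1, "pred2d", "theta_2dp", rng
        )

        self.pyr_blocks: list[list[nn.Conv3d]] = []
        self.pred_3d = None
        if config.use_3d_pyramid:
            pc = config.pyramid_channels
            pin = config.feature_width_out + config.n_classes
            for scale in range(2):
                block = []
                cin = pin
                for i in range(config.pyramid_convs_per_block):
                    block.append(
                        nn.Conv3d(
                            cin, pc, K3D, f"pyr{scale}.conv{i}", "theta_3d", rng
                        )
                    )
                    cin = pc
                self.pyr_blocks.append(block)
            self.pred_3d = nn.Conv3d(
                pc, config.n_classes, K1, "pred3d", "theta_3dp", rng
            )

    # -- forward -----------------------------------------------------------
    def forward_tensors(
        self, window: np.ndarray
    ) -> tuple[ag.Tensor, ag.Tensor | None]:
        """Run a (1, z, y, x) window; returns cropped (xhat_2d, xhat_3d) tensors."""
        window = np.asarray(window, dtype=np.float32)
        if window.ndim == 3:
            window = window[None]
        if window.ndim != 4 or window.shape[0] != 1:
            raise ValueError("input window must have shape (1, z, y, x)")
        _, _, y, x = window.shape
        depth = len(self.config.encoder_channels) - 1
        div = 2 ** depth
        if y % div or x % div or y < div or x < div:
            raise ValueError(
                f"lateral size ({y},{x}) must be a positive multiple of {div} "
                f"for the configured pooling depth"
            )
        t = ag.Tensor(window)
        skips: list[ag.Tensor] = []
        for s, block in enumerate(self.enc_blocks):
            for conv in block:
                t = ag.relu(conv(t))
            if s < len(self.enc_blocks) - 1:
                skips.append(t)
                t = ag.maxpool(t, (1, 2, 2))
        for up, block, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            t = ag.relu(up(t))
            t = ag.concat_channels([skip, t])
            for conv in block:
                t = ag.relu(conv(t))
        if self.feature_conv is not None:
            t = ag.relu(self.feature_conv(t))
        x2d = ag.softmax_channels(self.pred_2d(t))
        x3d = None
        if self.config.use_3d_pyramid:
            pin = ag.concat_channels([t, x2d])
            s0 = pin
            for conv in self.pyr_blocks[0]:
                s0 = ag.relu(conv(s0))
            s1 = ag.maxpool(pin, (1, 2, 2))
            for conv in self.pyr_blocks[1]:
                s1 = ag.relu(conv(s1))
            s1 = ag.upsample_nearest(s1, (1, 2, 2))
            x3d = ag.softmax_channels(self.pred_3d(s0 + s1))
            x3d = ag.crop_spatial(x3d, self.config.crop_margin)
        x2d = ag.crop_spatial(x2d, self.config.crop_margin)
        return x2d, x3d

    def forward(self, window: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Inference forward pass; returns numpy probability arrays."""
        with ag.no_grad():
            x2d, x3d = self.forward_tensors(window)
        return x2d.data, None if x3d is None else x3d.data

    @property
    def output_probs(self):
        """Index of the head producing the network's segmentation (3D if present)."""
        return 1 if self.config.use_3d_pyramid else 0


def build_network(config: ModelConfig | None = None) -> HybridNet:
    return HybridNet(config or ModelConfig())


def forward(network: HybridNet, window: np.ndarray):
    x2d, x3d = network.forward(window)
    return x2d, x3d


def partition_params(network: HybridNet) -> NetworkParams:
    """Partition all trainable variables into the four loss subsets."""
    parts = NetworkParams()
    buckets = {
        "theta_2d": parts.theta_2d,
        "theta_3d": parts.theta_3d,
        "theta_2dp": parts.theta_2dp,
        "theta_3dp": parts.theta_3dp,
    }
    for p in network.parameters():
        if p.group not in buckets:
            raise ValueError(f"parameter {p.name} has unknown subset {p.group!r}")
        buckets[p.group].append(p)
    n = sum(len(b) for b in buckets.values())
    if n != len(network.parameters()):
        raise ValueError("parameter partition is not exhaustive")
    return parts


def parameter_count(network: nn.Module) -> int:
    return int(sum(p.data.size for p in network.parameters()))


# -- checkpointing ---------------------------------------------------------
def save_checkpoint(path: str, network: HybridNet) -> None:
    """Store parameters plus the full model config for reproducible reload."""
    state = network.state_dict()
    cfg = json.dumps(asdict(network.config))
    np.savez(path, __model_config__=np.bytes_(cfg.encode()), **state)


def load_checkpoint(path: str) -> HybridNet:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__model_config__"]).decode())
        for key in ("encoder_channels", "crop_margin"):
            cfg_dict[key] = tuple(cfg_dict[key])
        net = HybridNet(ModelConfig(**cfg_dict))
        net.load_state_dict(
            {k: data[k] for k in data.files if k != "__model_config__"}
        )
    return net


# -- optional fully-3D U-Net baselines ------------------------------------
@dataclass
class UNet3DConfig:
    channels: tuple[int, ...] = (32, 64, 128)
    convs_per_block: int = 3
    pool: tuple[int, int, int] = (1, 2, 2)
    crop_margin: tuple[int, int, int] = (0, 2, 2)
    n_classes: int = N_CLASSES
    init_seed: int = 0


class UNet3D(nn.Module):
    """Same-padded fully-3D U-Net with 3 convolutions per block and 2 pools."""

    def __init__(self, config: UNet3DConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        ch = config.channels
        self.enc_blocks = []
        cin = 1
        for s in range(len(ch)):
            block = []
            for i in range(config.convs_per_block):
                block.append(
                    nn.Conv3d(cin, ch[s], K3D, f"enc{s}.conv{i}", "theta_3d", rng)
                )
                cin = ch[s]
            self.enc_blocks.append(block)
        self.upconvs = []
        self.dec_blocks = []
        for s in range(len(ch) - 2, -1, -1):
            self.upconvs.append(
                nn.ConvTranspose(
                    ch[s + 1], ch[s], config.pool, f"dec{s}.up", "theta_3d", rng
                )
            )
            block = []
            cin = 2 * ch[s]
            for i in range(config.convs_per_block):
                block.append(
                    nn.Conv3d(cin, ch[s], K3D, f"dec{s}.conv{i}", "theta_3d", rng)
                )
                cin = ch[s]
            self.dec_blocks.append(block)
        self.pred = nn.Conv3d(ch[0], config.n_classes, K1, "pred", "theta_3dp", rng)

    def forward_tensors(self, window: np.ndarray) -> tuple[ag.Tensor, None]:
        window = np.asarray(window, dtype=np.float32)
        if window.ndim == 3:
            window = window[None]
        t = ag.Tensor(window)
        skips = []
        for s, block in enumerate(self.enc_blocks):
            for conv in block:
                t = ag.relu(conv(t))
            if s < len(self.enc_blocks) - 1:
                skips.append(t)
                t = ag.maxpool(t, self.config.pool)
        for up, block, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            t = ag.relu(up(t))
            t = ag.concat_channels([skip, t])
            for conv in block:
                t = ag.relu(conv(t))
        probs = ag.softmax_channels(self.pred(t))
        return ag.crop_spatial(probs, self.config.crop_margin), None

    def forward(self, window: np.ndarray):
        with ag.no_grad():
            probs, _ = self.forward_tensors(window)
        return probs.data, None

    @property
    def output_probs(self):
        return 0


#: Window contracts of the two baseline variants.
UNET3D_VARIANTS = {
    "thin": UNet3DConfig(pool=(1, 2, 2), crop_margin=(0, 2, 2)),
    "thick": UNet3DConfig(pool=(2, 2, 2), crop_margin=(0, 0, 0)),
}


def build_3d_unet(
    variant: str, channels: tuple[int, ...] | None = None, init_seed: int = 0
) -> UNet3D:
    """Optional baseline hooks: 'thin' ((5,300,300)->(5,296,296), z untouched by
    pooling) or 'thick' ((16,180,180)->(16,180,180), pooling on all axes)."""
    if variant not in UNET3D_VARIANTS:
        raise ValueError(f"unknown 3D U-Net variant {variant!r}")
    base = UNET3D_VARIANTS[variant]
    cfg = UNet3DConfig(
        channels=channels or base.channels,
        pool=base.pool,
        crop_margin=base.crop_margin,
        init_seed=init_seed,
    )
    return UNet3D(cfg)
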