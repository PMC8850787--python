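"""The background-aware adversarial counting network.

Architecture (all fully convolutional):

* **encoder** ``FE`` — VGG16-style conv stages with three stride-2 max pools,
  producing feature maps ``M_f`` at 1/8 of the input resolution;
* **counting decoder** ``FD`` — a stack of dilated 3x3 convolutions (rate 2)
  refining ``M_f`` into counting features ``M_c``;
* **segmentation branch** ``FS`` — the same dilated stack ending in a
  2-channel softmax; the second channel is the soft foreground mask ``M_s``;
* **local count regressor** ``FC`` — consumes ``[M_s, M_c]`` (channel
  concatenation) and average-pools by 2 then 4, so each output cell predicts
  the object count of a 64x64 input patch;
* two patch-level **domain discriminators** — ``DF`` on ``M_f`` and ``DM`` on
  ``M_s`` — each two stride-2 convolutions plus a 1x1 softmax head, so every
  output cell classifies a 4x4 patch of its input as source or target.  Both
  sit behind a gradient reversal layer during training, which turns their
  classification loss into an adversarial alignment signal for the encoder
  and segmentation branch.

Two size profiles share all code paths: ``full`` (VGG16 channel widths) and
``tiny`` (small widths for CPU-scale experiments and tests).  An ablation
head (``head="density"``) replaces the pooling regressor with a
same-resolution convolutional density head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "ForwardOutputs",
    "BadaModel",
    "lambda_schedule",
    "grad_reverse",
]

grad_reverse = ad.grad_reverse  # re-exported: part of this module's surface


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters defining a :class:`BadaModel`.

    ``encoder_channels`` lists the conv widths of each of the three
    pooling stages; ``decoder_channels`` the dilated-conv widths shared by
    the counting decoder and segmentation branch.
    """

    profile: str = "tiny"
    encoder_channels: tuple = ((8,), (16,), (32,))
    decoder_channels: tuple = (32, 16)
    regressor_channels: tuple = (16, 16)
    disc_channels: int = 16
    dilation: int = 2
    head: str = "local_count"
    use_discriminators: bool = True
    use_pretrained_encoder: str | None = None
    grl_gamma: float = 10.0
    seed: int = 0

    @classmethod
    def tiny(cls, seed: int = 0, **kw) -> "ModelConfig":
        return replace(cls(seed=seed), **kw)

    @classmethod
    def full(cls, seed: int = 0, **kw) -> "ModelConfig":
        cfg = cls(
            profile="full",
            encoder_channels=((64, 64), (128, 128), (256, 256, 256), (512, 512, 512)),
            decoder_channels=(512, 512, 512, 256, 128, 64),
            regressor_channels=(64, 32),
            disc_channels=64,
            seed=seed,
        )
        return replace(cfg, **kw)

    def __post_init__(self):
        if self.profile not in ("full", "tiny"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.head not in ("local_count", "density"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.grl_gamma <= 0:
            raise ValueError("grl_gamma must be positive")


class _Conv:
    """Conv layer: holds weight/bias Tensors and the conv hyperparameters."""

    def __init__(self, rng, c_in, c_out, k=3, stride=1, dilation=1):
        std = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Tensor(rng.normal(0.0, std, size=(c_out, c_in, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.dilation = stride, dilation
        self.padding = None if stride == 1 else dilation * (k - 1) // 2

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(
            x, self.weight, self.bias,
            stride=self.stride, dilation=self.dilation, padding=self.padding,
        )

    @property
    def params(self):
        return [self.weight, self.bias]


def _stack_params(layers):
    out = []
    for layer in layers:
        out.extend(layer.params)
    return out


@dataclass
class ForwardOutputs:
    """Tensors produced by one full forward pass (batch NCHW layout)."""

    m_f: Tensor                  # features, (N, C, H/8, W/8)
    m_c: Tensor                  # counting features
    seg_probs: Tensor            # (N, 2, H/8, W/8) softmax
    m_s: Tensor                  # foreground channel, (N, 1, H/8, W/8)
    c_est: Tensor | None         # (N, 1, H/64, W/64) local counts, or None
    density: Tensor | None       # (N, 1, H/8, W/8) for the density head
    disc_f: Tensor | None        # (N, 2, H/32, W/32) domain class map on M_f
    disc_m: Tensor | None        # same, on M_s

    @property
    def prediction(self) -> Tensor:
        out = self.c_est if self.c_est is not None else self.density
        assert out is not None
        return out


class BadaModel:
    """Encoder + two-branch decoder + count regressor + two discriminators.

    All randomness in initialisation is driven by ``config.seed``; each
    component draws from its own spawned stream, so e.g. disabling the
    discriminators leaves every other component's initial weights unchanged.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        streams = {
            name: np.random.default_rng(child)
            for name, child in zip(
                ("encoder", "decoder", "segment", "regressor", "disc_f", "disc_m"),
                ss.spawn(6),
            )
        }
        self._build_encoder(streams["encoder"])
        self._build_decoders(streams["decoder"], streams["segment"])
        self._build_head(streams["regressor"])
        self._build_discriminators(streams["disc_f"], streams["disc_m"])
        if config.use_pretrained_encoder:
            self._load_encoder_weights(config.use_pretrained_encoder)

    # -- construction ---------------------------------------------------------
    def _build_encoder(self, rng):
        cfg = self.config
        self.encoder_stages = []
        c_in = 3
        for stage in cfg.encoder_channels:
            layers = []
            for c_out in stage:
                layers.append(_Conv(rng, c_in, c_out))
                c_in = c_out
            self.encoder_stages.append(layers)
        n_pools = min(3, len(self.encoder_stages))
        if n_pools != 3:
            raise ValueError("encoder must contain at least 3 stages (3 stride-2 pools)")
        self.feature_channels = c_in

    def _dilated_stack(self, rng, final_channels):
        cfg = self.config
        layers = []
        c_in = self.feature_channels
        for c_out in cfg.decoder_channels:
            layers.append(_Conv(rng, c_in, c_out, dilation=cfg.dilation))
            c_in = c_out
        head = _Conv(rng, c_in, final_channels, k=1) if final_channels else None
        return layers, head

    def _build_decoders(self, rng_dec, rng_seg):
        self.decoder_layers, _ = self._dilated_stack(rng_dec, 0)
        self.segment_layers, self.segment_head = self._dilated_stack(rng_seg, 2)
        self.counting_channels = self.config.decoder_channels[-1]

    def _build_head(self, rng):
        # same three convs serve both heads; only the pooling between them
        # differs (local_count pools by 2 then 4, density does not pool)
        cfg = self.config
        c_in = self.counting_channels + 1  # [M_s, M_c]
        h1, h2 = cfg.regressor_channels
        self.regressor = [
            _Conv(rng, c_in, h1),
            _Conv(rng, h1, h2),
            _Conv(rng, h2, 1, k=1),
        ]

    def _build_discriminators(self, rng_f, rng_m):
        cfg = self.config
        k = cfg.disc_channels

        def make(rng, c_in):
            return [
                _Conv(rng, c_in, k, stride=2),
                _Conv(rng, k, k, stride=2),
                _Conv(rng, k, 2, k=1),
            ]

        self.disc_f_layers = make(rng_f, self.feature_channels)
        self.disc_m_layers = make(rng_m, 1)

    def _load_encoder_weights(self, path: str):
        """Load encoder conv weights from a local .npz archive.

        Arrays must be named ``stage{i}_conv{j}_weight`` / ``_bias`` and match
        the configured shapes.  (Pretrained backbones are an optional input;
        nothing in this package downloads weights.)
        """
        archive = np.load(path)
        for i, stage in enumerate(self.encoder_stages):
            for j, conv in enumerate(stage):
                w = archive[f"stage{i}_conv{j}_weight"]
                b = archive[f"stage{i}_conv{j}_bias"]
                if w.shape != conv.weight.data.shape:
                    raise ValueError(
                        f"pretrained weight stage{i}_conv{j} has shape {w.shape}, "
                        f"expected {conv.weight.data.shape}"
                    )
                conv.weight.data = np.asarray(w, dtype=np.float64)
                conv.bias.data = np.asarray(b, dtype=np.float64)

    # -- parameter access -----------------------------------------------------
    def encoder_parameters(self):
        return _stack_params(layer for stage in self.encoder_stages for layer in stage)

    def main_parameters(self):
        params = self.encoder_parameters()
        params += _stack_params(self.decoder_layers)
        params += _stack_params(self.segment_layers) + self.segment_head.params
        params += _stack_params(self.regressor)
        return params

    def discriminator_parameters(self):
        return _stack_params(self.disc_f_layers) + _stack_params(self.disc_m_layers)

    def parameters(self):
        params = self.main_parameters()
        if self.config.use_discriminators:
            params += self.discriminator_parameters()
        return params

    # -- forward components ---------------------------------------------------
    @staticmethod
    def _to_batch(image) -> Tensor:
        """Accept HxWx3, NxHxWx3 (channels-last) or an NCHW Tensor."""
        if isinstance(image, Tensor):
            return image
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"expected (H, W, 3) or (N, H, W, 3) image, got {arr.shape}")
        return Tensor(arr.transpose(0, 3, 1, 2))

    def encode(self, image) -> Tensor:
        """FE: image -> M_f at 1/8 resolution."""
        x = self._to_batch(image)
        H, W = x.shape[2], x.shape[3]
        if H % 8 or W % 8:
            raise ValueError(
                f"input size {H}x{W} not divisible by 8; pad to "
                f"{-H % 8} extra row(s) and {-W % 8} column(s)"
            )
        for i, stage in enumerate(self.encoder_stages):
            for conv in stage:
                x = ad.relu(conv(x))
            if i < 3:
                x = ad.max_pool2d(x, 2)
        return x

    def decode_counting(self, feat: Tensor) -> Tensor:
        """FD: M_f -> counting features M_c (same spatial size)."""
        x = feat
        for conv in self.decoder_layers:
            x = ad.relu(conv(x))
        return x

    def segment(self, feat: Tensor) -> Tensor:
        """FS: M_f -> 2-channel softmax segmentation map."""
        x = feat
        for conv in self.segment_layers:
            x = ad.relu(conv(x))
        return ad.softmax_channels(self.segment_head(x))

    @staticmethod
    def foreground_channel(seg_probs: Tensor) -> Tensor:
        """M_s: the second softmax channel (foreground probability)."""
        return _channel_slice(seg_probs, 1)

    def regress_local_counts(self, m_c: Tensor, m_s: Tensor) -> Tensor:
        """FC: [M_s, M_c] -> local count map at 1/64 of the input image."""
        if m_c.shape[2:] != m_s.shape[2:]:
            raise ValueError(f"spatial mismatch: M_c {m_c.shape} vs M_s {m_s.shape}")
        x = ad.concat_channels(m_s, m_c)
        conv1, conv2, conv3 = self.regressor
        x = ad.relu(conv1(x))
        x = ad.avg_pool2d(x, 2)
        x = ad.relu(conv2(x))
        x = ad.avg_pool2d(x, 4)
        return ad.softplus(conv3(x))

    def regress_density(self, m_c: Tensor, m_s: Tensor) -> Tensor:
        """Ablation head: same-resolution per-pixel density at 1/8 scale."""
        if m_c.shape[2:] != m_s.shape[2:]:
            raise ValueError(f"spatial mismatch: M_c {m_c.shape} vs M_s {m_s.shape}")
        x = ad.concat_channels(m_s, m_c)
        conv1, conv2, conv3 = self.regressor
        x = ad.relu(conv1(x))
        x = ad.relu(conv2(x))
        return ad.softplus(conv3(x))

    def _discriminate(self, layers, x: Tensor) -> Tensor:
        if x.shape[2] < 4 or x.shape[3] < 4:
            raise ValueError(f"discriminator input {x.shape[2]}x{x.shape[3]} smaller than 4x4")
        conv1, conv2, conv3 = layers
        x = ad.relu(conv1(x))
        x = ad.relu(conv2(x))
        return ad.softmax_channels(conv3(x))

    def discriminate_features(self, m_f: Tensor) -> Tensor:
        """DF: per-cell source/target class map; one cell per 4x4 M_f patch."""
        return self._discriminate(self.disc_f_layers, m_f)

    def discriminate_mask(self, m_s: Tensor) -> Tensor:
        """DM: domain class map over the soft foreground mask."""
        return self._discriminate(self.disc_m_layers, m_s)

    @staticmethod
    def source_probability(class_map: Tensor) -> Tensor:
        """A_est: channel 1 of a domain class map (source-domain probability)."""
        return _channel_slice(class_map, 1)

    # -- full pass ------------------------------------------------------------
    def forward_full(self, image, lam: float = 0.0, with_discriminators: bool | None = None
                     ) -> ForwardOutputs:
        """Compose the full model; discriminators see GRL(·, ``lam``) inputs."""
        if with_discriminators is None:
            with_discriminators = self.config.use_discriminators
        x = self._to_batch(image)
        H, W = x.shape[2], x.shape[3]
        if self.config.head == "local_count" and (H % 64 or W % 64):
            raise ValueError(f"input size {H}x{W} must be divisible by 64")
        m_f = self.encode(x)
        m_c = self.decode_counting(m_f)
        seg = self.segment(m_f)
        m_s = _channel_slice(seg, 1)
        c_est = density = None
        if self.config.head == "local_count":
            c_est = self.regress_local_counts(m_c, m_s)
        else:
            density = self.regress_density(m_c, m_s)
        disc_f = disc_m = None
        if with_discriminators:
            disc_f = self.discriminate_features(ad.grad_reverse(m_f, lam))
            disc_m = self.discriminate_mask(ad.grad_reverse(m_s, lam))
        return ForwardOutputs(m_f, m_c, seg, m_s, c_est, density, disc_f, disc_m)

    def predict(self, image) -> np.ndarray:
        """Local count map (or density map) for one image, as a 2-D array.

        Runs graph-free (inference mode), so it is safe for large inputs.
        """
        with ad.no_grad():
            out = self.forward_full(image, lam=0.0, with_discriminators=False)
        return out.prediction.data[0, 0].copy()


def _channel_slice(x: Tensor, c: int) -> Tensor:
    """Select one channel of an NCHW tensor, keeping a channel axis of 1."""
    out = ad._node(x.data[:, c : c + 1], (x,))
    if out._parents:

        def backward(g):
            gx = np.zeros_like(x.data)
            gx[:, c : c + 1] = g
            ad._accum(x, gx)

        out._backward = backward
    return out


def lambda_schedule(p: float, gamma: float = 10.0) -> float:
    """Adversarial-weight ramp: λ(p) = 2 / (1 + exp(−γ·p)) − 1.

    ``p`` is the fraction of training elapsed in [0, 1]; λ rises smoothly
    from 0 towards (but never reaching) 1, easing the discriminators in so
    adversarial gradients do not destabilise early counting training.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if p < 0.0 or p > 1.0:
        warnings.warn(f"training fraction p={p} outside [0, 1]; clamped", stacklevel=2)
        p = min(max(p, 0.0), 1.0)
    return float(2.0 / (1.0 + np.exp(-gamma * p)) - 1.0)
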