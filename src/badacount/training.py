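"""Adversarial training loop for cross-domain counting.

Each optimisation step consumes a paired batch — labelled source crops and
unlabelled target crops.  Source crops contribute the counting loss (L1 on
local count maps) and the segmentation loss (cross-entropy against the
pseudo foreground mask); both domains feed the two discriminators through
the gradient reversal layer, whose weight λ ramps up over training via
:func:`badacount.network.lambda_schedule`.  A single SGD pass then realises
the min–max game: discriminator parameters descend the domain loss while the
encoder and segmentation branch ascend it through the reversed gradient.

The optimiser is SGD with momentum; the learning rate decays stepwise at
configured epochs.  Every source of randomness (batch order, crops, flips)
derives from ``TrainConfig.seed``, so training histories are bitwise
reproducible on a fixed platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.transform import resize as _resize

from .autodiff import SGD
from .losses import LossValues, adversarial_loss, counting_loss, make_domain_labels, segmentation_loss
from .network import BadaModel, ModelConfig, lambda_schedule
from .targets import (
    DotAnnotationSet,
    default_threshold,
    downsample_mask,
    make_density_map,
    make_foreground_mask,
    make_local_count_map,
)

__all__ = [
    "TrainConfig",
    "DomainBatch",
    "augment",
    "build_batch",
    "train_step",
    "fit",
    "learning_rate_at",
]

#: side of the image patch that one local-count cell covers
LOCAL_COUNT_PATCH = 64
#: resolution reduction of the segmentation branch
SEG_DOWNSAMPLE = 8


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults are the full-scale schedule (500 epochs, lr 0.01 decayed 10x at
    epochs 250 and 400, 512-pixel crops); :meth:`desk` returns the CPU-scale
    variant used by the synthetic experiments (64-pixel crops, 30 epochs).
    """

    epochs: int = 500
    lr: float = 0.01
    lr_decay_epochs: tuple[int, ...] = (250, 400)
    lr_decay_factor: float = 10.0
    momentum: float = 0.9
    weight_decay: float = 0.0
    crop: int = 512
    resize_factor: float = 1.0
    batch_size: int = 2          # images per domain per step
    gamma: float = 10.0          # λ-schedule steepness
    sigma: float = 8.0           # density-map Gaussian spread, pixels
    t_c: float | None = None     # mask threshold; None = 5% of kernel peak
    seed: int = 0

    def __post_init__(self):
        if self.crop % LOCAL_COUNT_PATCH:
            raise ValueError(f"crop must be divisible by {LOCAL_COUNT_PATCH}")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "TrainConfig":
        cfg = cls(
            epochs=30, crop=64, batch_size=2, sigma=4.0,
            lr_decay_epochs=(), seed=seed,
        )
        return replace(cfg, **kw)

    @property
    def threshold(self) -> float:
        return self.t_c if self.t_c is not None else default_threshold(self.sigma)


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Learning rate in force during 1-based ``epoch``."""
    decays = sum(1 for e in config.lr_decay_epochs if epoch >= e)
    return config.lr / config.lr_decay_factor**decays


@dataclass
class DomainBatch:
    """One step's paired mini-batches (NHWC images, NCHW target grids)."""

    source_images: np.ndarray       # (B, crop, crop, 3)
    source_count_maps: np.ndarray   # (B, 1, crop/64, crop/64)
    source_masks: np.ndarray        # (B, 1, crop/8, crop/8) in {0, 1}
    target_images: np.ndarray       # (B, crop, crop, 3)


def augment(
    image: np.ndarray,
    dots: DotAnnotationSet,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, DotAnnotationSet]:
    """Resize, random-crop and random-flip an image with its dots.

    Dots falling outside the crop window are dropped; a horizontal flip
    mirrors the surviving x coordinates.  Images smaller than the crop after
    resizing are reflect-padded with a warning.
    """
    img = np.asarray(image, dtype=np.float64)
    pts = dots.points.copy()
    if config.resize_factor != 1.0:
        f = config.resize_factor
        new_hw = (max(1, round(img.shape[0] * f)), max(1, round(img.shape[1] * f)))
        img = _resize(img, new_hw + (3,), order=1, mode="reflect", anti_aliasing=f < 1.0)
        pts = pts * f

    H, W = img.shape[:2]
    c = config.crop
    if H < c or W < c:
        pad_h, pad_w = max(0, c - H), max(0, c - W)
        warnings.warn(
            f"image {H}x{W} smaller than crop {c}; reflect-padding", stacklevel=2
        )
        img = np.pad(img, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
        H, W = img.shape[:2]

    oy = int(rng.integers(0, H - c + 1))
    ox = int(rng.integers(0, W - c + 1))
    img = img[oy : oy + c, ox : ox + c]
    if len(pts):
        pts = pts - np.array([ox, oy])
        keep = (pts[:, 0] >= 0) & (pts[:, 0] < c) & (pts[:, 1] >= 0) & (pts[:, 1] < c)
        pts = pts[keep]

    if rng.random() < 0.5:
        img = img[:, ::-1].copy()
        if len(pts):
            # pixel-centre mirror; dots in the last half-pixel clamp to the edge
            pts[:, 0] = np.clip((c - 1) - pts[:, 0], 0.0, c - 1)

    return img, DotAnnotationSet(dots.image_id, pts, (c, c))


def _source_targets(dots: DotAnnotationSet, config: TrainConfig, head: str):
    density = make_density_map(dots, config.sigma)
    mask = make_foreground_mask(density, config.threshold)
    mask_lo = downsample_mask(mask, SEG_DOWNSAMPLE)
    patch = LOCAL_COUNT_PATCH if head == "local_count" else SEG_DOWNSAMPLE
    counts = make_local_count_map(density, patch, patch)
    return counts.values, mask_lo.values.astype(np.float64)


def build_batch(
    source_dataset,
    target_dataset,
    config: TrainConfig,
    rng: np.random.Generator,
    head: str = "local_count",
) -> DomainBatch:
    """Sample, augment and rasterise one paired source/target batch."""
    B = config.batch_size
    src_idx = rng.integers(0, len(source_dataset), size=B)
    tgt_idx = rng.integers(0, len(target_dataset), size=B)
    s_imgs, s_counts, s_masks, t_imgs = [], [], [], []
    for i in src_idx:
        img, dots = augment(source_dataset.images[i], source_dataset.dots[i], config, rng)
        counts, mask = _source_targets(dots, config, head)
        s_imgs.append(img)
        s_counts.append(counts[None])
        s_masks.append(mask[None])
    for i in tgt_idx:
        img, _ = augment(
            target_dataset.images[i],
            DotAnnotationSet("unlabeled", np.empty((0, 2)), target_dataset.images[i].shape[:2]),
            config,
            rng,
        )
        t_imgs.append(img)
    return DomainBatch(
        np.stack(s_imgs), np.stack(s_counts), np.stack(s_masks), np.stack(t_imgs)
    )


def train_step(
    model: BadaModel,
    batch: DomainBatch,
    lam: float,
    optimizer: SGD,
) -> LossValues:
    """One combined optimisation step over a paired batch.

    Source images contribute counting + segmentation losses; both domains'
    features and soft masks feed the discriminators through GRL(·, λ), so a
    single backward pass updates discriminators towards better domain
    classification and the encoder/segmentation branch towards confusing
    them.  With λ = 0 the adversarial gradient into the main branch is
    exactly zero while the discriminators still learn.
    """
    adversarial = model.config.use_discriminators
    out_s = model.forward_full(batch.source_images, lam=lam, with_discriminators=adversarial)
    l_c = counting_loss(out_s.prediction, batch.source_count_maps)
    l_s = segmentation_loss(out_s.m_s, batch.source_masks)
    total = l_c + l_s
    l_a_value = 0.0
    if adversarial:
        out_t = model.forward_full(batch.target_images, lam=lam, with_discriminators=True)
        l_a_src = adversarial_loss(
            model.source_probability(out_s.disc_f),
            model.source_probability(out_s.disc_m),
            make_domain_labels("source", out_s.disc_f.shape[-2:])[None, None],
        )
        l_a_tgt = adversarial_loss(
            model.source_probability(out_t.disc_f),
            model.source_probability(out_t.disc_m),
            make_domain_labels("target", out_t.disc_f.shape[-2:])[None, None],
        )
        l_a = (l_a_src + l_a_tgt) * 0.5
        l_a_value = float(l_a)
        total = total + l_a

    if not np.isfinite(float(total)):
        raise FloatingPointError(
            f"non-finite loss (L_c={float(l_c)}, L_s={float(l_s)}, L_a={l_a_value})"
        )
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return LossValues(float(l_c), float(l_s), float(l_a_value))


def fit(
    source_dataset,
    target_dataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[BadaModel, pd.DataFrame]:
    """Train a model on a labelled-source / unlabelled-target pair.

    λ is updated once at the start of each epoch from the elapsed-training
    fraction; the returned history has one row per epoch with the λ, the
    learning rate and the mean of each loss over the epoch's steps.
    """
    if len(source_dataset) == 0 or len(target_dataset) == 0:
        raise ValueError("source and target datasets must be non-empty")
    model = BadaModel(model_config)
    optimizer = SGD(
        model.parameters(),
        lr=train_config.lr,
        momentum=train_config.momentum,
        weight_decay=train_config.weight_decay,
    )
    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed))
    steps = max(1, len(source_dataset) // train_config.batch_size)
    rows = []
    for epoch in range(train_config.epochs):
        lam = (
            lambda_schedule(epoch / train_config.epochs, train_config.gamma)
            if model_config.use_discriminators
            else 0.0
        )
        optimizer.lr = learning_rate_at(epoch + 1, train_config)
        sums = np.zeros(3)
        for _ in range(steps):
            batch = build_batch(
                source_dataset, target_dataset, train_config, rng, head=model_config.head
            )
            losses = train_step(model, batch, lam, optimizer)
            sums += (losses.counting, losses.segmentation, losses.adversarial)
        rows.append(
            {
                "epoch": epoch,
                "lambda": lam,
                "lr": optimizer.lr,
                "L_c": sums[0] / steps,
                "L_s": sums[1] / steps,
                "L_a": sums[2] / steps,
            }
        )
    return model, pd.DataFrame(rows)
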