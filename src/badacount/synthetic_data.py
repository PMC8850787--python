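"""Synthetic two-domain plant-field image generator.

Real cross-domain counting studies contrast fields that differ in object
scale (acquisition distance), hue/illumination (cultivar, growth stage) and
background clutter.  This generator renders controllable stand-ins: textured
elliptical "plants" on a textured soil background, with exact dot
annotations at object centres and a pixel-true foreground mask.  A *domain*
is a :class:`DomainSpec`; a domain **gap** is two specs differing along one
or more axes.

Distractors are plant-coloured but elongated, grass-like streaks that are
deliberately *not* annotated and *not* in the foreground mask: they are the
background elements that draw false counts out of a source-trained model,
the failure mode the background-aware adaptation is designed to fix.

Appearance is deliberately simple — the goal is controllable domain gaps on
a CPU budget, not photorealism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import ellipse as _draw_ellipse
from skimage.transform import resize as _resize

from .targets import DotAnnotationSet, ForegroundMask

__all__ = [
    "DomainSpec",
    "SyntheticDataset",
    "render_scene",
    "make_domain_pair",
    "get_preset",
    "PRESETS",
    "mean_color_distance",
]


@dataclass(frozen=True)
class DomainSpec:
    """Rendering parameters of one imaging domain.

    ``n_objects`` is an inclusive integer range; ``object_radius`` is
    (mean, sd) in pixels; ``object_eccentricity`` in [0, 1) elongates
    ellipses at constant area (0 = circle); ``distractor_density`` is the
    expected number of non-annotated plant-coloured streaks per image.
    """

    n_objects: tuple[int, int] = (5, 12)
    object_radius: tuple[float, float] = (5.0, 1.0)
    object_hue: tuple[float, float, float] = (0.22, 0.52, 0.16)
    object_eccentricity: float = 0.25
    background_color: tuple[float, float, float] = (0.38, 0.30, 0.22)
    distractor_density: float = 0.0
    illumination_gain: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.object_radius[0] <= 0:
            raise ValueError("object radius mean must be positive")
        if self.distractor_density < 0:
            raise ValueError("distractor density must be >= 0")
        if self.illumination_gain <= 0:
            raise ValueError("illumination gain must be positive")
        if not (0 <= self.object_eccentricity < 1):
            raise ValueError("eccentricity must be in [0, 1)")


@dataclass
class SyntheticDataset:
    """Images with exact dot annotations and pixel-true foreground masks."""

    images: list[np.ndarray]
    dots: list[DotAnnotationSet]
    masks: list[ForegroundMask]
    spec: DomainSpec

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_size(self) -> tuple[int, int]:
        return self.images[0].shape[:2]


def _background(spec: DomainSpec, H: int, W: int, rng) -> np.ndarray:
    base = np.asarray(spec.background_color, dtype=np.float64)
    coarse = rng.normal(0.0, 0.05, size=(max(H // 16, 2), max(W // 16, 2)))
    texture = _resize(coarse, (H, W), order=1, mode="reflect", anti_aliasing=False)
    img = base[None, None, :] * (1.0 + texture[:, :, None])
    return img


def _draw_blob(img, mask_out, cy, cx, r_minor, r_major, rotation, color, rng):
    rr, cc = _draw_ellipse(cy, cx, r_minor, r_major, rotation=rotation, shape=img.shape[:2])
    if rr.size == 0:
        return rr, cc
    shade = 0.85 + 0.3 * rng.random(rr.size)  # per-pixel leaf texture
    img[rr, cc] = np.asarray(color)[None, :] * shade[:, None]
    if mask_out is not None:
        mask_out[rr, cc] = 1
    return rr, cc


def render_scene(spec: DomainSpec, H: int, W: int, rng: np.random.Generator):
    """Render one field image.

    Returns ``(image, dots, true_mask)``: an ``(H, W, 3)`` float image in
    [0, 1], the dot annotations at exact object centres, and the pixel-true
    object mask (distractor pixels excluded).  Fully determined by ``rng``.
    """
    if H < 64 or W < 64:
        raise ValueError("image must be at least 64x64")
    img = _background(spec, H, W, rng)
    mask = np.zeros((H, W), dtype=np.uint8)

    n = int(rng.integers(spec.n_objects[0], spec.n_objects[1] + 1))
    mean_r, sd_r = spec.object_radius
    q = 1.0 - spec.object_eccentricity
    hue = np.asarray(spec.object_hue, dtype=np.float64)

    # place objects with pairwise separation so instances never merge
    placed: list[tuple[float, float, float]] = []  # (cy, cx, extent)
    radii = np.clip(rng.normal(mean_r, sd_r, size=n), 1.5, None)
    kept = []
    for r in radii:
        extent = r / np.sqrt(q)  # major semi-axis at constant area
        ok = False
        for _ in range(200):
            cy = rng.uniform(extent + 2, H - extent - 3)
            cx = rng.uniform(extent + 2, W - extent - 3)
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 > (extent + pe + 2.0) ** 2
                for py, px, pe in placed
            ):
                ok = True
                break
        if not ok:
            continue
        placed.append((cy, cx, extent))
        kept.append((cy, cx, r))
    if len(kept) < n:
        warnings.warn(
            f"could only place {len(kept)} of {n} objects without collisions",
            stacklevel=2,
        )

    # distractors first so objects render on top of them; they mimic plants
    # (same hue, compact) but are smaller and more elongated — weed clumps
    n_distr = int(rng.poisson(spec.distractor_density))
    for _ in range(n_distr):
        cy = rng.uniform(2, H - 3)
        cx = rng.uniform(2, W - 3)
        r_d = rng.uniform(0.45, 0.65) * mean_r
        q_d = 0.45  # more eccentric than true plants
        rot = rng.uniform(0, np.pi)
        _draw_blob(
            img, None, cy, cx, r_d * np.sqrt(q_d), r_d / np.sqrt(q_d), rot,
            hue * rng.uniform(0.85, 1.05), rng,
        )

    dots = []
    for cy, cx, r in kept:
        rot = rng.uniform(0, np.pi)
        _draw_blob(
            img, mask, cy, cx, r * np.sqrt(q), r / np.sqrt(q), rot,
            hue * rng.uniform(0.92, 1.08), rng,
        )
        dots.append((cx, cy))

    img *= spec.illumination_gain
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    annotations = DotAnnotationSet("synthetic", np.asarray(dots, dtype=np.float64).reshape(-1, 2), (H, W))
    return img, annotations, ForegroundMask(mask)


def _render_dataset(spec: DomainSpec, n_images: int, H: int, W: int) -> SyntheticDataset:
    children = np.random.SeedSequence(spec.seed).spawn(n_images)
    images, dots, masks = [], [], []
    for i, child in enumerate(children):
        img, d, m = render_scene(spec, H, W, np.random.default_rng(child))
        images.append(img)
        dots.append(replace_image_id(d, f"img_{i:04d}"))
        masks.append(m)
    return SyntheticDataset(images, dots, masks, spec)


def replace_image_id(dots: DotAnnotationSet, image_id: str) -> DotAnnotationSet:
    return DotAnnotationSet(image_id, dots.points, dots.image_size)


def make_domain_pair(
    source: DomainSpec, target: DomainSpec, n_images: int, H: int, W: int
) -> tuple[SyntheticDataset, SyntheticDataset, dict]:
    """Render a labelled source and an unlabelled target dataset.

    The two specs must differ in at least one field (otherwise there is no
    gap to adapt across).  Returns the datasets plus a manifest recording
    both specs; image-level seeds derive deterministically from each spec's
    ``seed``.
    """
    if source == target:
        raise ValueError("source and target specs are identical: no domain gap")
    src = _render_dataset(source, n_images, H, W)
    tgt = _render_dataset(target, n_images, H, W)
    manifest = {
        "n_images": n_images,
        "image_size": [H, W],
        "source": _spec_dict(source),
        "target": _spec_dict(target),
    }
    return src, tgt, manifest


def _spec_dict(spec: DomainSpec) -> dict:
    return {
        "n_objects": list(spec.n_objects),
        "object_radius": list(spec.object_radius),
        "object_hue": list(spec.object_hue),
        "object_eccentricity": spec.object_eccentricity,
        "background_color": list(spec.background_color),
        "distractor_density": spec.distractor_density,
        "illumination_gain": spec.illumination_gain,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }


#: preset name -> the DomainSpec fields in which target differs from source
PRESETS: dict[str, dict] = {
    # acquisition-distance gap: target plants at half the linear scale
    "scale_shift": {"object_radius": (2.5, 0.5)},
    # cultivar/growth-stage gap: yellower plants under dimmer illumination
    "hue_shift": {"object_hue": (0.34, 0.48, 0.10), "illumination_gain": 0.72},
    # background-clutter gap: plant-coloured grass streaks in the target only
    "distractor_shift": {"distractor_density": 10.0},
}


def get_preset(name: str, seed: int = 0) -> tuple[DomainSpec, DomainSpec]:
    """Source/target spec pair for a named domain-gap preset.

    The source spec is the default :class:`DomainSpec`; the target differs
    exactly in the fields listed in :data:`PRESETS` (plus its seed, so the
    two domains never share image-level randomness).
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    source = DomainSpec(seed=seed)
    target = replace(source, seed=seed + 1_000_003, **PRESETS[name])
    return source, target


def mean_color_distance(a: SyntheticDataset, b: SyntheticDataset) -> float:
    """Euclidean distance between the datasets' mean RGB values.

    A cheap one-number domain-gap summary: near zero for identically
    distributed domains, clearly positive under a hue/illumination shift.
    """
    ma = np.mean([img.mean(axis=(0, 1)) for img in a.images], axis=0)
    mb = np.mean([img.mean(axis=(0, 1)) for img in b.images], axis=0)
    return float(np.linalg.norm(ma - mb))
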