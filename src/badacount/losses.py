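"""Training objectives: L1 counting loss, cross-entropy segmentation loss,
and the two-discriminator adversarial domain loss.

All three losses are means over the elements of their operand grids and are
differentiable through the package's autodiff engine: each function accepts
either plain arrays or :class:`~badacount.autodiff.Tensor` predictions and
returns a scalar Tensor (``float()``-convertible).

Domain-label convention: source = 1, target = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, binary_cross_entropy, mean_abs_error

__all__ = [
    "LossValues",
    "counting_loss",
    "segmentation_loss",
    "adversarial_loss",
    "make_domain_labels",
    "CLAMP_EPS",
]

#: probability clamp used inside every cross-entropy to avoid log(0)
CLAMP_EPS = 1e-7


@dataclass(frozen=True)
class LossValues:
    """Scalar values of the three objectives for one step or epoch."""

    counting: float
    segmentation: float
    adversarial: float

    def __post_init__(self):
        for name in ("counting", "segmentation", "adversarial"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} loss must be finite and >= 0, got {v}")


def counting_loss(c_est, c_gt) -> Tensor:
    """Mean absolute error between estimated and ground-truth local counts."""
    c_est = as_tensor(c_est)
    return mean_abs_error(c_est, np.asarray(c_gt, dtype=np.float64))


def segmentation_loss(s_est, s_gt) -> Tensor:
    """Mean binary cross-entropy of foreground probabilities against a 0/1 mask."""
    s_est = as_tensor(s_est)
    return binary_cross_entropy(s_est, np.asarray(s_gt, dtype=np.float64), eps=CLAMP_EPS)


def adversarial_loss(a_est_f, a_est_m, a_gt) -> Tensor:
    """Sum of the feature- and mask-discriminator cross-entropies.

    ``a_est_f`` and ``a_est_m`` hold each discriminator's per-cell probability
    that its input came from the source domain; ``a_gt`` is the domain label
    map (broadcast to each estimate's shape).  Each term is averaged over its
    own grid and the two are summed.
    """
    a_est_f = as_tensor(a_est_f)
    a_est_m = as_tensor(a_est_m)
    a_gt = np.asarray(a_gt, dtype=np.float64)
    try:
        gt_f = np.broadcast_to(a_gt, a_est_f.shape)
        gt_m = np.broadcast_to(a_gt, a_est_m.shape)
    except ValueError as exc:
        raise ValueError(
            f"domain labels of shape {a_gt.shape} do not broadcast to "
            f"{a_est_f.shape} / {a_est_m.shape}"
        ) from exc
    return binary_cross_entropy(a_est_f, gt_f, eps=CLAMP_EPS) + binary_cross_entropy(
        a_est_m, gt_m, eps=CLAMP_EPS
    )


def make_domain_labels(domain: str, shape) -> np.ndarray:
    """Constant domain-label map: all ones for source, all zeros for target."""
    shape = tuple(int(s) for s in np.atleast_1d(shape))
    if any(s <= 0 for s in shape):
        raise ValueError("label map shape must be positive")
    if domain == "source":
        return np.ones(shape, dtype=np.float64)
    if domain == "target":
        return np.zeros(shape, dtype=np.float64)
    raise ValueError(f"unknown domain {domain!r}; expected 'source' or 'target'")
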