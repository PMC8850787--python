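"""Counting evaluation metrics, including the decoupled MAE (DMAE).

Besides the standard aggregate metrics (MAE, MSE, MAPE, R²), counting models
are evaluated with a *decoupled* MAE: per image, the absolute count error is
computed separately over background and foreground regions (split by the
pseudo foreground mask) and the two are summed.  A model that hallucinates
counts on background while missing true objects can score a deceptively low
MAE — the background false positives cancel the misses — but its DMAE stays
honest, since DMAE >= MAE by the per-image triangle inequality.

MSE here is the mean of squared errors as printed in the counting
literature's metric definition; the square root is additionally reported as
RMSE since some papers tabulate the rooted quantity under the same name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .targets import ForegroundMask, make_density_map, make_foreground_mask

__all__ = [
    "CountingReport",
    "basic_metrics",
    "split_counts",
    "dmae",
    "expand_local_counts",
    "evaluate_model",
]


def basic_metrics(estimates, truths) -> tuple[float, float, float, float | None]:
    """MAE, MSE, MAPE (percent) and R² over per-image total counts.

    MAPE terms with a zero true count are skipped with a warning.  R² is
    ``None`` (with a warning) when all true counts are equal, since its
    denominator vanishes.
    """
    est = np.asarray(estimates, dtype=np.float64).ravel()
    tru = np.asarray(truths, dtype=np.float64).ravel()
    if est.size != tru.size or est.size == 0:
        raise ValueError("estimates and truths must be equal-length and non-empty")
    err = est - tru
    mae = float(np.abs(err).mean())
    mse = float((err**2).mean())
    nz = tru != 0
    if not nz.all():
        warnings.warn(
            f"MAPE: skipped {int((~nz).sum())} sample(s) with zero true count",
            stacklevel=2,
        )
    mape = float((np.abs(err[nz]) / tru[nz]).mean() * 100.0) if nz.any() else float("nan")
    ss_tot = float(((tru - tru.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("R²: undefined (all true counts equal)", stacklevel=2)
        r2 = None
    else:
        r2 = float(1.0 - (err**2).sum() / ss_tot)
    return mae, mse, mape, r2


def expand_local_counts(values: np.ndarray, patch: tuple[int, int]) -> np.ndarray:
    """Spread each local-count cell uniformly over its pixel patch.

    Turns a patch-level count grid into a per-pixel density with the same
    total, so the foreground/background split (defined over pixels) applies
    to local-count predictions as well.
    """
    h, w = patch
    v = np.asarray(values, dtype=np.float64)
    return np.kron(v, np.ones((h, w))) / (h * w)


def split_counts(d_est: np.ndarray, s_gt: ForegroundMask | np.ndarray) -> tuple[float, float]:
    """Split a per-pixel density total into (foreground, background) parts.

    Background is the zero set of the mask; the two parts sum to the map
    total exactly.
    """
    mask = s_gt.values if isinstance(s_gt, ForegroundMask) else np.asarray(s_gt)
    d = np.asarray(d_est, dtype=np.float64)
    if d.shape != mask.shape:
        raise ValueError(f"density {d.shape} and mask {mask.shape} shapes differ")
    fg = float(d[mask != 0].sum())
    bg = float(d[mask == 0].sum())
    return fg, bg


def dmae(est_splits, true_splits) -> float:
    """Decoupled MAE: mean over images of |ŷ_b − y_b| + |ŷ_f − y_f|.

    ``est_splits`` and ``true_splits`` are sequences of per-image
    ``(foreground, background)`` pairs produced by :func:`split_counts` with
    the *same* pseudo mask for estimate and truth.
    """
    est = np.asarray(est_splits, dtype=np.float64).reshape(-1, 2)
    tru = np.asarray(true_splits, dtype=np.float64).reshape(-1, 2)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("split lists must be equal-length and non-empty")
    return float(np.abs(est - tru).sum(axis=1).mean())


@dataclass
class CountingReport:
    """Per-image counts and error decomposition plus aggregate metrics."""

    image_ids: list[str]
    estimates: np.ndarray        # ŷ_n
    truths: np.ndarray           # y_n
    est_splits: np.ndarray       # (n, 2) of (ŷ_f, ŷ_b)
    true_splits: np.ndarray      # (n, 2) of (y_f, y_b)
    mae: float = field(init=False)
    mse: float = field(init=False)
    rmse: float = field(init=False)
    mape: float = field(init=False)
    r2: float | None = field(init=False)
    dmae: float = field(init=False)

    def __post_init__(self):
        self.estimates = np.asarray(self.estimates, dtype=np.float64)
        self.truths = np.asarray(self.truths, dtype=np.float64)
        self.est_splits = np.asarray(self.est_splits, dtype=np.float64).reshape(-1, 2)
        self.true_splits = np.asarray(self.true_splits, dtype=np.float64).reshape(-1, 2)
        for tot, parts, what in (
            (self.estimates, self.est_splits, "estimated"),
            (self.truths, self.true_splits, "true"),
        ):
            if not np.allclose(parts.sum(axis=1), tot, atol=1e-6, rtol=1e-6):
                raise ValueError(f"{what} splits do not sum to totals")
        self.mae, self.mse, self.mape, self.r2 = basic_metrics(self.estimates, self.truths)
        self.rmse = float(np.sqrt(self.mse))
        self.dmae = dmae(self.est_splits, self.true_splits)

    def to_frame(self) -> pd.DataFrame:
        """Per-image rows followed by an aggregate row."""
        rows = pd.DataFrame(
            {
                "image": self.image_ids,
                "y_est": self.estimates,
                "y_true": self.truths,
                "y_est_fg": self.est_splits[:, 0],
                "y_est_bg": self.est_splits[:, 1],
                "y_true_fg": self.true_splits[:, 0],
                "y_true_bg": self.true_splits[:, 1],
            }
        )
        agg = pd.DataFrame(
            [
                {
                    "image": "<aggregate>",
                    "y_est": self.estimates.mean(),
                    "y_true": self.truths.mean(),
                    "MAE": self.mae,
                    "MSE": self.mse,
                    "RMSE": self.rmse,
                    "MAPE_percent": self.mape,
                    "R2": np.nan if self.r2 is None else self.r2,
                    "DMAE": self.dmae,
                }
            ]
        )
        return pd.concat([rows, agg], ignore_index=True)

    def summary(self) -> dict:
        return {
            "MAE": self.mae,
            "MSE": self.mse,
            "RMSE": self.rmse,
            "MAPE_percent": self.mape,
            "R2": self.r2,
            "DMAE": self.dmae,
            "mean_est_bg": float(self.est_splits[:, 1].mean()),
            "mean_true_bg": float(self.true_splits[:, 1].mean()),
            "n_images": int(self.estimates.size),
        }


def evaluate_model(model, images, dots_list, sigma: float, t_c: float) -> CountingReport:
    """Run a trained model over a dataset and build a counting report.

    Predictions (local count maps, or 1/8-scale density maps for the density
    head) are expanded to per-pixel densities before the
    foreground/background split; truths are the Gaussian density maps built
    from the dots with the same σ, split by the same pseudo mask, so per
    image y_n = y_f,n + y_b,n exactly.  The pseudo mask is thresholded at
    ``t_c`` as during training.
    """
    patch = 64 if getattr(model.config, "head", "local_count") == "local_count" else 8
    ids, est, tru, est_sp, tru_sp = [], [], [], [], []
    for image, dots in zip(images, dots_list):
        pred = model.predict(image)
        d_est = expand_local_counts(pred, (patch, patch))
        d_gt = make_density_map(dots, sigma)
        s_gt = make_foreground_mask(d_gt, t_c)
        if d_est.shape != d_gt.values.shape:
            # partial trailing patches carry no prediction; crop truth to match
            d_gt_vals = d_gt.values[: d_est.shape[0], : d_est.shape[1]]
            mask_vals = s_gt.values[: d_est.shape[0], : d_est.shape[1]]
        else:
            d_gt_vals, mask_vals = d_gt.values, s_gt.values
        f_e, b_e = split_counts(d_est, mask_vals)
        f_t, b_t = split_counts(d_gt_vals, mask_vals)
        ids.append(dots.image_id)
        est.append(f_e + b_e)
        tru.append(f_t + b_t)
        est_sp.append((f_e, b_e))
        tru_sp.append((f_t, b_t))
    return CountingReport(ids, est, tru, est_sp, tru_sp)
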