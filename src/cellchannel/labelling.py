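"""Marker-based cell gating with a two-component Gaussian mixture.

For every cell the total flattened marker intensity l_i is summed over the
pixels strictly closer than 30 px to the crop center, and the gating
statistic is the log intensity relative to the experiment-wide maximum:

    F_i = ln(l_i / max_j l_j)

A two-component univariate Gaussian mixture is fitted to the pooled F values
of one experiment (all dishes).  Cells whose posterior probability is below
0.8 in both components are labelled "unused"; of the rest, the high-mean
component is the marker-positive proB-like class and the low-mean component
the LMPP-like class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

LABEL_LMPP = "LMPP-like"
LABEL_PROB = "proB-like"
LABEL_UNUSED = "unused"

MARKER_RADIUS = 30
POSTERIOR_THRESHOLD = 0.8
_SD_FLOOR = 1e-4


def _disc_mask(shape: tuple[int, int], radius: float,
               center: tuple[int, int]) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 < radius**2


def marker_total(record_or_crop, radius: float = MARKER_RADIUS) -> float:
    """Total flattened marker intensity strictly within ``radius`` px of the
    crop center (pixel (75, 75) of the 150x150 crop).

    Accepts a CellRecord (uses its "marker_flat" crop) or a bare 2D crop.
    A non-positive total marks the cell for exclusion (returned as-is; the
    caller drops it).
    """
    if hasattr(record_or_crop, "crops"):
        crop = record_or_crop.crops[("marker_flat", 0, 0)]
    else:
        crop = np.asarray(record_or_crop)
    mask = _disc_mask(crop.shape, radius,
                      (crop.shape[0] // 2, crop.shape[1] // 2))
    total = float(crop[mask].sum())
    if total <= 0:
        logger.debug("non-positive marker total %g; cell excluded", total)
    return total


def log_relative_intensity(l: np.ndarray) -> np.ndarray:
    """F_i = ln(l_i) - ln(max_j l_j), pooled over the whole experiment."""
    l = np.asarray(l, dtype=np.float64)
    if l.size == 0:
        raise ValueError("empty intensity vector")
    if (l <= 0).any():
        raise ValueError("all marker totals must be positive")
    return np.log(l) - np.log(l.max())


@dataclass
class LabelModel:
    """Fitted mixture over F with the component-to-type assignment."""

    means: tuple[float, float]       # (low, high)
    sds: tuple[float, float]
    weights: tuple[float, float]
    unused_interval: tuple[float, float]
    n_cells: int
    converged: bool
    seed: int
    threshold: float = POSTERIOR_THRESHOLD

    def posterior_high(self, F: np.ndarray) -> np.ndarray:
        """Posterior probability of the high-mean (proB-like) component."""
        F = np.atleast_1d(np.asarray(F, dtype=np.float64))
        log_p = []
        for mu, sd, w in zip(self.means, self.sds, self.weights):
            log_p.append(np.log(w) - 0.5 * np.log(2 * np.pi * sd**2)
                         - (F - mu) ** 2 / (2 * sd**2))
        log_p = np.stack(log_p)
        log_p -= log_p.max(axis=0, keepdims=True)
        p = np.exp(log_p)
        return p[1] / p.sum(axis=0)

    def label(self, F: np.ndarray) -> np.ndarray:
        """Posterior >= threshold in a component labels the cell; else unused."""
        p_high = self.posterior_high(F)
        out = np.full(p_high.shape, LABEL_UNUSED, dtype=object)
        out[p_high >= self.threshold] = LABEL_PROB
        out[1 - p_high >= self.threshold] = LABEL_LMPP
        return out

    def to_dict(self) -> dict:
        return {
            "means": list(self.means), "sds": list(self.sds),
            "weights": list(self.weights),
            "unused_interval": list(self.unused_interval),
            "n_cells": self.n_cells, "converged": self.converged,
            "seed": self.seed, "threshold": self.threshold,
        }


def fit_label_gmm(F: np.ndarray, threshold: float = POSTERIOR_THRESHOLD,
                  seed: int = 0) -> tuple[LabelModel, np.ndarray]:
    """EM fit of a 2-component mixture on F and per-cell labels.

    k-means initialisation with a fixed seed, 500-iteration cap, 1e-6
    log-likelihood tolerance.  Raises on non-convergence or a degenerate
    component.
    """
    F = np.asarray(F, dtype=np.float64)
    if np.unique(F).size < 2:
        raise ValueError("need at least 2 distinct F values to fit the mixture")
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         max_iter=500, tol=1e-6, n_init=1,
                         init_params="kmeans", random_state=seed)
    gm.fit(F.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge in 500 iterations; lower bound "
            f"{gm.lower_bound_:.6g}, n={F.size}")
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    if (sds < _SD_FLOOR).any():
        raise RuntimeError(f"degenerate mixture component (sd {sds.min():.3g})")
    order = np.argsort(means)  # low (LMPP-like) first, high (proB-like) second
    model = LabelModel(
        means=tuple(means[order]), sds=tuple(sds[order]),
        weights=tuple(gm.weights_.ravel()[order]),
        unused_interval=(0.0, 0.0), n_cells=int(F.size),
        converged=True, seed=seed, threshold=threshold)
    model.unused_interval = _unused_interval(model, F)
    return model, model.label(F)


def _unused_interval(model: LabelModel, F: np.ndarray) -> tuple[float, float]:
    """F range where both posteriors are below the threshold.

    Located on a dense grid spanning the observed F range; for a mixture
    with distinct means this is a single interval between the means.
    """
    lo = min(F.min(), model.means[0]) - 1.0
    hi = max(F.max(), model.means[1]) + 1.0
    grid = np.linspace(lo, hi, 8001)
    p_high = model.posterior_high(grid)
    both_low = (p_high < model.threshold) & (1 - p_high < model.threshold)
    if not both_low.any():
        mid = (model.means[0] + model.means[1]) / 2
        return (mid, mid)
    return (float(grid[both_low].min()), float(grid[both_low].max()))


def label_records(records, threshold: float = POSTERIOR_THRESHOLD,
                  seed: int = 0, radius: float = MARKER_RADIUS) -> LabelModel:
    """Gate a whole experiment's records in place.

    Computes l_i and F_i (experiment-wide max), drops cells with
    non-positive totals, fits the mixture and writes F, posterior and label
    back into each record.  Returns the fitted LabelModel.
    """
    totals = np.array([marker_total(r, radius) for r in records])
    keep = totals > 0
    if not keep.all():
        logger.info("excluding %d cells with non-positive marker totals",
                    int((~keep).sum()))
    kept = [r for r, k in zip(records, keep) if k]
    F = log_relative_intensity(totals[keep])
    model, labels = fit_label_gmm(F, threshold=threshold, seed=seed)
    p_high = model.posterior_high(F)
    for rec, f, p, lab in zip(kept, F, p_high, labels):
        rec.F = float(f)
        rec.posterior_prob = float(p)
        rec.label = str(lab)
    for rec, k in zip(records, keep):
        if not k:
            rec.label = LABEL_UNUSED
    return model
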