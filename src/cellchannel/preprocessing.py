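"""Pre-classifier transforms: circular masking, mean-1 normalisation and
balanced trimming.

Crops are masked with a circle of radius 50 px around the crop center
(outside set to 0), the mean of the inside-mask pixels is scaled to 1 per
channel, and per-dish class counts are trimmed by uniform random choice to
the common minimum C* = min over (dish, type) of C_{dish,type}, so every
dish contributes the same number of cells of each type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

logger = logging.getLogger(__name__)

MASK_RADIUS = 50
CROP_SIZE = 150


@lru_cache(maxsize=8)
def circular_mask(radius: int = MASK_RADIUS, size: int = CROP_SIZE) -> np.ndarray:
    """Boolean disc: pixels strictly closer than ``radius`` to the center."""
    c = size // 2
    yy, xx = np.ogrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 < radius**2


def apply_circular_mask(crop: np.ndarray, radius: int = MASK_RADIUS) -> np.ndarray:
    """Zero all pixels at distance >= radius from the crop center."""
    crop = np.asarray(crop)
    if crop.shape != (CROP_SIZE, CROP_SIZE):
        raise ValueError(f"expected a {CROP_SIZE}x{CROP_SIZE} crop, got {crop.shape}")
    out = np.where(circular_mask(radius, CROP_SIZE), crop, 0)
    return out.astype(np.float64)


def normalize_mean(masked_crop: np.ndarray, radius: int = MASK_RADIUS
                   ) -> np.ndarray | None:
    """Scale so the inside-mask mean is 1; outside stays 0.

    Returns None (cell excluded) when the inside-mask mean is not positive.
    """
    crop = np.asarray(masked_crop, dtype=np.float64)
    mask = circular_mask(radius, CROP_SIZE)
    m = crop[mask].mean()
    if m <= 0:
        logger.debug("non-positive inside-mask mean %g; cell excluded", m)
        return None
    out = crop / m
    out[~mask] = 0.0
    return out


def preprocess_crop(crop: np.ndarray, radius: int = MASK_RADIUS
                    ) -> np.ndarray | None:
    """Mask then normalise one channel crop (the full transform chain)."""
    return normalize_mean(apply_circular_mask(crop, radius), radius)


@dataclass
class BalancedDataset:
    """Cell ids per (dish, type) after trimming to the common count C*."""

    cells: dict[tuple[int, str], list[int]]
    common_count: int
    seed: int

    @property
    def all_ids(self) -> list[int]:
        out: list[int] = []
        for key in sorted(self.cells):
            out.extend(self.cells[key])
        return out

    def n_total(self) -> int:
        return sum(len(v) for v in self.cells.values())


def trim_to_balance(cell_ids: dict[tuple[int, str], list[int]],
                    seed: int = 0) -> BalancedDataset:
    """Uniform random subsample without replacement of every (dish, type)
    list down to C* = min over (dish, type) counts; reproducible from seed."""
    for key, ids in cell_ids.items():
        if len(ids) == 0:
            raise ValueError(f"empty (dish, type) group {key}: cannot balance")
    cstar = min(len(ids) for ids in cell_ids.values())
    rng = np.random.default_rng(seed)
    trimmed: dict[tuple[int, str], list[int]] = {}
    for key in sorted(cell_ids):
        ids = np.asarray(cell_ids[key])
        pick = rng.choice(len(ids), size=cstar, replace=False)
        trimmed[key] = sorted(int(i) for i in ids[pick])
    return BalancedDataset(cells=trimmed, common_count=cstar, seed=seed)


def group_labelled_records(records) -> dict[tuple[int, str], list[int]]:
    """(dish, label) -> cell ids for non-unused labelled records."""
    from cellchannel.labelling import LABEL_LMPP, LABEL_PROB

    groups: dict[tuple[int, str], list[int]] = {}
    for r in records:
        if r.label in (LABEL_LMPP, LABEL_PROB):
            groups.setdefault((r.dish_id, r.label), []).append(r.cell_id)
    return groups
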