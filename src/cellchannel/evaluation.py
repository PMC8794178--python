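"""Dish-level cross-validation, ROC/AUC, and the experiment grid.

Each culture dish serves once as the held-out test set ("validation n tests
dish n"), so the reported AUC reflects between-batch generalisation.  The
AUC is the Mann–Whitney pair statistic — the probability that a random
positive (proB-like) cell scores above a random negative one, ties counted
half — computed from midranks.  The positive class is proB-like, scored by
its softmax probability (CNN) or the SVM decision value.

The grid runner evaluates many input configurations (single channels,
channel combinations, contour-only, cell-size SVM, focal offsets, training
set sizes, init seeds) on the *same* balanced cell set, so configurations
are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from cellchannel.classifiers import (
    CNNSpec,
    TrainSpec,
    predict_proba,
    train_cnn,
    train_svm_size,
)
from cellchannel.labelling import LABEL_PROB
from cellchannel.preprocessing import BalancedDataset, preprocess_crop

logger = logging.getLogger(__name__)


def compute_auc(scores, truth) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)  # midranks
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class ChannelConfig:
    """Input planes for the classifier: (channel, focal index, time index).

    The special channel name "contour" selects the binary contour crop.
    The fluorescence marker channel defines the labels and is never a
    classifier input.
    """

    name: str
    planes: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        for ch, _, _ in self.planes:
            if ch.startswith("marker"):
                raise ValueError(
                    "the marker channel defines the labels and cannot be a "
                    "classifier input")

    @property
    def n_channels(self) -> int:
        return len(self.planes)

    @classmethod
    def single(cls, channel: str, focal: int = 0, time: int = 0) -> "ChannelConfig":
        return cls(name=channel, planes=((channel, focal, time),))

    @classmethod
    def combo(cls, channels, focal: int = 0, time: int = 0) -> "ChannelConfig":
        return cls(name="+".join(channels),
                   planes=tuple((c, focal, time) for c in channels))


@dataclass
class EvaluationResult:
    """Per-validation AUCs and ROC curves for one configuration."""

    config_name: str
    validations: list[dict]   # test_dish, auc, fpr, tpr, n_train, n_test, ...

    @property
    def aucs(self) -> np.ndarray:
        return np.array([v["auc"] for v in self.validations])

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())


def build_input_stack(records, config: ChannelConfig) -> np.ndarray:
    """(N, C, 150, 150) float32 classifier input: mask + mean-1 normalise
    every plane of every record (the contour channel included)."""
    n = len(records)
    out = np.zeros((n, config.n_channels, 150, 150), dtype=np.float32)
    for i, rec in enumerate(records):
        for j, (ch, fi, ti) in enumerate(config.planes):
            crop = rec.contour if ch == "contour" else rec.crops[(ch, fi, ti)]
            pre = preprocess_crop(np.asarray(crop, dtype=np.float64))
            if pre is None:
                logger.debug("cell %d plane %s: empty after masking", rec.cell_id, ch)
                continue
            out[i, j] = pre
    return out


def _select_balanced(records, balanced: BalancedDataset):
    by_id = {r.cell_id: r for r in records}
    selected = [by_id[cid] for cid in balanced.all_ids]
    y = np.array([int(r.label == LABEL_PROB) for r in selected])
    dishes = np.array([r.dish_id for r in selected])
    return selected, y, dishes


def crossvalidate(records, balanced: BalancedDataset,
                  config: ChannelConfig | None = None,
                  classifier: str = "cnn",
                  train_spec: TrainSpec | None = None) -> EvaluationResult:
    """Leave-one-dish-out evaluation of one configuration.

    ``classifier`` is "cnn" (requires ``config``) or "svm_size" (uses the
    cell areas; ``config`` ignored).
    """
    selected, y, dishes = _select_balanced(records, balanced)
    dish_ids = np.unique(dishes)
    if len(dish_ids) < 2:
        raise ValueError("dish-level cross-validation needs at least 2 dishes")
    ts = train_spec or TrainSpec()
    x = areas = None
    if classifier == "cnn":
        if config is None:
            raise ValueError("a ChannelConfig is required for the CNN")
        x = build_input_stack(selected, config)
    elif classifier == "svm_size":
        areas = np.array([r.area_px for r in selected], dtype=np.float64)
    else:
        raise ValueError(f"unknown classifier kind {classifier!r}")

    validations = []
    for dish in dish_ids:
        test = dishes == dish
        if np.unique(y[test]).size < 2:
            raise ValueError(f"test dish {dish} contains a single class")
        if classifier == "cnn":
            trained = train_cnn(x[~test], y[~test],
                                spec=CNNSpec(in_channels=config.n_channels),
                                train_spec=ts)
            scores = predict_proba(trained, x[test])[:, 1]
            extra = {"epochs_run": trained.epochs_run,
                     "best_epoch": trained.best_epoch}
        else:
            svm = train_svm_size(areas[~test], y[~test])
            scores = svm.decision_values(areas[test])
            extra = {}
        fpr, tpr, _ = roc_curve(y[test], scores)
        validations.append({
            "test_dish": int(dish), "auc": compute_auc(scores, y[test]),
            "fpr": fpr, "tpr": tpr, "n_train": int((~test).sum()),
            "n_test": int(test.sum()), "scores": scores, "truth": y[test],
            **extra})
    name = config.name if (classifier == "cnn" and config) else classifier
    return EvaluationResult(config_name=name, validations=validations)


def permutation_null_mean_auc(result: EvaluationResult, n_perm: int = 2000,
                              seed: int = 0) -> np.ndarray:
    """Permutation distribution of the mean per-dish AUC under the null.

    Labels are permuted within each validation's test set while its scores
    are held fixed, preserving the class balance and score distribution.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for b in range(n_perm):
        aucs = []
        for v in result.validations:
            perm = rng.permutation(v["truth"])
            aucs.append(compute_auc(v["scores"], perm))
        out[b] = np.mean(aucs)
    return out


def paired_permutation_pvalue(aucs_a, aucs_b, n_perm: int = 10000,
                              seed: int = 0) -> float:
    """Sign-flip permutation p-value for a paired AUC difference."""
    d = np.asarray(aucs_a, dtype=np.float64) - np.asarray(aucs_b, dtype=np.float64)
    rng = np.random.default_rng(seed)
    obs = abs(d.mean())
    flips = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = np.abs((flips * d).mean(axis=1))
    return float((np.sum(null >= obs - 1e-15) + 1) / (n_perm + 1))


def run_grid(records, balanced: BalancedDataset, plan: list[dict],
             train_spec: TrainSpec | None = None) -> tuple[pd.DataFrame, dict]:
    """Evaluate a list of configurations on the same balanced cell set.

    Each plan entry: {"name", "kind": "cnn"|"svm_size", "channels": [...],
    "focal": int, "time": int, "seeds": [init seeds]}.  Returns a tidy
    long-format table (configuration, test_dish, seed, auc) and a dict of
    the full EvaluationResults keyed by (name, seed).
    """
    ts = train_spec or TrainSpec()
    rows = []
    results = {}
    for entry in plan:
        name = entry["name"]
        kind = entry.get("kind", "cnn")
        seeds = entry.get("seeds", [ts.init_seed])
        config = None
        if kind == "cnn":
            config = ChannelConfig.combo(entry["channels"],
                                         focal=entry.get("focal", 0),
                                         time=entry.get("time", 0))
        for s in seeds:
            spec_s = TrainSpec(**{**ts.__dict__, "init_seed": int(s)})
            res = crossvalidate(records, balanced, config=config,
                                classifier=kind, train_spec=spec_s)
            results[(name, s)] = res
            for v in res.validations:
                rows.append({"configuration": name, "seed": int(s),
                             "test_dish": v["test_dish"], "auc": v["auc"],
                             "n_train": v["n_train"], "n_test": v["n_test"]})
    return pd.DataFrame(rows), results


def summarize_grid(table: pd.DataFrame) -> pd.DataFrame:
    """Per-configuration mean AUC, between-dish sd and between-seed sd."""
    out = []
    for name, g in table.groupby("configuration"):
        dish_means = g.groupby("test_dish").auc.mean()
        seed_means = g.groupby("seed").auc.mean()
        out.append({
            "configuration": name, "mean_auc": g.auc.mean(),
            "between_dish_sd": float(dish_means.std(ddof=1)) if len(dish_means) > 1 else 0.0,
            "between_seed_sd": float(seed_means.std(ddof=1)) if len(seed_means) > 1 else 0.0,
            "n_rows": len(g)})
    return pd.DataFrame(out)


def size_sweep(records, balanced: BalancedDataset, config: ChannelConfig,
               sizes, seeds, test_dish: int,
               train_spec: TrainSpec | None = None) -> pd.DataFrame:
    """Training-set-size sweep with a fixed held-out test dish.

    For each seed, training subsets of increasing size are *nested* random
    samples (stratified by class) from the pooled non-test dishes, and every
    size is evaluated on the identical test set; sizes above the available
    pool are clipped with a warning.
    """
    selected, y, dishes = _select_balanced(records, balanced)
    ts = train_spec or TrainSpec()
    x = build_input_stack(selected, config)
    test = dishes == test_dish
    pool = np.flatnonzero(~test)
    rows = []
    for s in seeds:
        rng = np.random.default_rng(int(s) + 7919)
        by_class = {c: rng.permutation(pool[y[pool] == c])
                    for c in np.unique(y[pool])}
        for size in sizes:
            n = int(size)
            if n > len(pool):
                logger.warning("training size %d exceeds pool %d; clipped",
                               n, len(pool))
                n = len(pool)
            half = n // 2
            idx = np.concatenate([by_class[0][:half], by_class[1][:n - half]])
            spec_s = TrainSpec(**{**ts.__dict__, "init_seed": int(s)})
            trained = train_cnn(x[idx], y[idx],
                                spec=CNNSpec(in_channels=config.n_channels),
                                train_spec=spec_s)
            scores = predict_proba(trained, x[test])[:, 1]
            rows.append({"configuration": config.name, "train_size": n,
                         "seed": int(s), "test_dish": int(test_dish),
                         "auc": compute_auc(scores, y[test]),
                         "train_ids": tuple(int(i) for i in np.sort(idx)),
                         "test_n": int(test.sum())})
    return pd.DataFrame(rows)
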