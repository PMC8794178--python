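"""End-to-end orchestration: simulate -> segment -> crop -> label ->
preprocess -> train/evaluate, with run-manifest bookkeeping.

The manifest records the configuration, the per-stage cell counts (cropped
>= labelled >= used for training — the attrition audit), the fitted gating
model and the evaluation table, plus a deterministic hash so identical
configurations produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from cellchannel.config import PipelineConfig
from cellchannel.cropping import crop_field, flatten_marker_channel, records_manifest
from cellchannel.evaluation import run_grid, summarize_grid
from cellchannel.labelling import LABEL_LMPP, LABEL_PROB, label_records
from cellchannel.preprocessing import group_labelled_records, trim_to_balance
from cellchannel.segmentation import segment_field
from cellchannel.synthetic import generate_experiment

logger = logging.getLogger(__name__)


def segment_and_crop(fields, config: PipelineConfig):
    """Segment every field's phase-contrast plane and crop all cells."""
    seg = config.segmentation
    records = []
    next_id = 0
    for image, _truth in fields:
        regions = segment_field(
            image.plane("ph"), polarity=seg.polarity,
            closing_radius=seg.closing_radius,
            smoothing_sigma=seg.smoothing_sigma,
            min_peak_distance=seg.min_peak_distance,
            min_px=seg.min_area_px, max_px=seg.max_area_px)
        flat = flatten_marker_channel(image.plane("marker"),
                                      sigma=config.labelling.flatten_sigma)
        recs = crop_field(image, regions, channels=config.crop_channels,
                          first_cell_id=next_id, flatten_marker=False)
        for r in recs:
            r0 = r.center[0] - 75
            c0 = r.center[1] - 75
            r.crops[("marker_flat", 0, 0)] = flat[r0:r0 + 150, c0:c0 + 150].copy()
        next_id += len(regions.table)
        records.extend(recs)
        logger.info("dish %d field %d: %d regions, %d cropped",
                    image.dish_id, image.field_id, len(regions.table), len(recs))
    return records


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    config.synthetic.validate()
    fields = generate_experiment(config.synthetic)
    records = segment_and_crop(fields, config)
    n_cropped = len(records)

    model = label_records(records,
                          threshold=config.labelling.posterior_threshold,
                          seed=config.labelling.gmm_seed,
                          radius=config.labelling.radius_px)
    n_labelled = sum(r.label in (LABEL_LMPP, LABEL_PROB) for r in records)

    groups = group_labelled_records(records)
    balanced = trim_to_balance(groups, seed=config.trim_seed)
    n_used = balanced.n_total()
    logger.info("counts: cropped %d, labelled %d, used %d",
                n_cropped, n_labelled, n_used)

    table, _results = run_grid(records, balanced, [dict(p) for p in config.plan],
                               train_spec=config.training)
    summary = summarize_grid(table)

    import cellchannel

    manifest = {
        "version": cellchannel.__version__,
        "config": config.to_dict(),
        "counts": {"cropped": n_cropped, "labelled": n_labelled,
                   "used_for_training": n_used,
                   "placement_failures": int(sum(t.n_placement_failures
                                                 for _, t in fields))},
        "label_model": model.to_dict(),
        "results": table.drop(columns=[c for c in ("fpr", "tpr")
                                       if c in table.columns]).to_dict("records"),
        "summary": summary.to_dict("records"),
    }
    manifest["manifest_hash"] = manifest_hash(manifest)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=_jsonable))
        records_manifest(records).to_csv(out / "cells.csv", index=False)
        table.to_csv(out / "results.csv", index=False)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def manifest_hash(manifest: dict) -> str:
    """Deterministic digest of a manifest (hash field itself excluded)."""
    payload = {k: v for k, v in manifest.items() if k != "manifest_hash"}
    blob = json.dumps(payload, sort_keys=True, default=_jsonable)
    return hashlib.sha256(blob.encode()).hexdigest()
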