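"""Shared fixtures: small synthetic experiments processed once per session.

The expensive fixtures (generation + segmentation + cropping + gating) are
session-scoped so the classifier-level tests and the acceptance suite reuse
the same processed cell records.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellchannel.config import PipelineConfig
from cellchannel.labelling import label_records
from cellchannel.pipeline import segment_and_crop
from cellchannel.preprocessing import group_labelled_records, trim_to_balance
from cellchannel.synthetic import SyntheticConfig, generate_experiment, null_config

#: strong-effect study conditions at reduced scale: both cell types inside
#: the (2000, 8000) px area band, a clear size difference and a strong
#: texture difference aligned with the marker, ~35 cells per 1024^2 field.
STRONG_CONFIG = SyntheticConfig(
    n_dishes=3, fields_per_dish=3, field_shape=(1024, 1024),
    cells_per_field=35, touching_fraction=0.1,
    size_means=(3200.0, 5200.0), texture_effect=2.0,
    placement_margin_px=80, seed=11)

#: identical scale with every classifier-visible effect removed
NULL_CONFIG = null_config(
    n_dishes=3, fields_per_dish=3, field_shape=(1024, 1024),
    cells_per_field=35, touching_fraction=0.1,
    placement_margin_px=80, seed=21)


def _process(config: SyntheticConfig):
    pcfg = PipelineConfig(synthetic=config)
    fields = generate_experiment(config)
    records = segment_and_crop(fields, pcfg)
    model = label_records(records)
    balanced = trim_to_balance(group_labelled_records(records), seed=0)
    return fields, records, model, balanced


@pytest.fixture(scope="session")
def strong_pipeline():
    """(fields, labelled records, label model, balanced set), strong effects."""
    return _process(STRONG_CONFIG)


@pytest.fixture(scope="session")
def null_pipeline():
    """Same, with null image effects (marker gating still informative)."""
    return _process(NULL_CONFIG)


@pytest.fixture(scope="session")
def small_field():
    """One 768^2 field with 12 well-separated cells and its ground truth."""
    cfg = SyntheticConfig(n_dishes=1, fields_per_dish=1,
                          field_shape=(768, 768), cells_per_field=12,
                          touching_fraction=0.0, placement_margin_px=80,
                          seed=42)
    return generate_experiment(cfg)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
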