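"""Generator contracts: determinism, ground-truth bookkeeping, effect nulls."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from cellchannel.synthetic import (
    SyntheticConfig,
    TYPE_PROB,
    draw_marker_log_totals,
    generate_experiment,
    generate_field,
    null_config,
)


def small_cfg(**kw):
    base = dict(n_dishes=1, fields_per_dish=1, field_shape=(640, 640),
                cells_per_field=8, touching_fraction=0.0,
                placement_margin_px=40, seed=5)
    base.update(kw)
    return SyntheticConfig(**base)


def test_empty_field_has_background_only():
    cfg = small_cfg(cells_per_field=0)
    img, truth = generate_field(cfg, 1, 1, np.random.SeedSequence(0))
    assert len(truth.cells) == 0
    assert truth.label_mask.max() == 0
    ph = img.plane("ph")
    assert ph.std() < 0.1 * ph.mean()  # noise around a flat background


def test_label_mask_components_match_ground_truth():
    """Without touching pairs the mask has exactly one connected component
    per cell and component areas equal the recorded true areas."""
    cfg = small_cfg(cells_per_field=50, field_shape=(1600, 1600), seed=9)
    img, truth = generate_field(cfg, 1, 1, np.random.SeedSequence(1))
    assert len(truth.cells) == 50
    # flood-fill oracle: scipy connected-component labelling of the binary mask
    comp, n = ndi.label(truth.label_mask > 0,
                        ndi.generate_binary_structure(2, 2))
    assert n == 50
    mask_areas = np.sort(np.bincount(truth.label_mask.ravel())[1:])
    assert np.array_equal(mask_areas, np.sort(truth.cells.area_px.to_numpy()))


def test_label_mask_ids_bijective_with_cells():
    cfg = small_cfg(cells_per_field=20, field_shape=(1100, 1100),
                    touching_fraction=0.3)
    img, truth = generate_field(cfg, 1, 1, np.random.SeedSequence(3))
    ids_in_mask = set(np.unique(truth.label_mask)) - {0}
    assert ids_in_mask == set(range(1, len(truth.cells) + 1))


def test_experiment_bookkeeping_and_determinism():
    cfg = small_cfg(n_dishes=3, fields_per_dish=2, cells_per_field=6)
    fields_a = generate_experiment(cfg)
    fields_b = generate_experiment(cfg)
    assert len(fields_a) == 6
    total = sum(len(t.cells) for _, t in fields_a)
    failures = sum(t.n_placement_failures for _, t in fields_a)
    assert total + failures == 3 * 2 * 6
    for (ia, ta), (ib, tb) in zip(fields_a, fields_b):
        for ch in ia.channels:
            assert np.array_equal(ia.channels[ch], ib.channels[ch])
        assert ta.cells.equals(tb.cells)
        assert np.array_equal(ta.label_mask, tb.label_mask)


def test_marker_separation_in_pooled_sd_units():
    """At separation 6 and unit log-sd the per-type empirical log totals
    are ~6 pooled-sd apart."""
    cfg = SyntheticConfig(marker_separation=6.0, marker_sd=1.0)
    rng = np.random.default_rng(0)
    types = rng.integers(0, 2, 4000)
    logs = draw_marker_log_totals(rng, types, cfg)
    gap = logs[types == 1].mean() - logs[types == 0].mean()
    pooled = np.sqrt((logs[types == 1].var() + logs[types == 0].var()) / 2)
    assert gap / pooled == pytest.approx(6.0, abs=0.3)


def test_marker_bimodality_few_cells_between_modes():
    """At separation/sd >= 4 the gating statistic is bimodal: fewer than 5%
    of cells land in the ambiguous region between the modes (the band where
    neither mixture component reaches 80% posterior)."""
    from cellchannel.labelling import (LABEL_UNUSED, fit_label_gmm,
                                       log_relative_intensity)

    cfg = SyntheticConfig(marker_separation=4.0, marker_sd=1.0)
    rng = np.random.default_rng(1)
    types = rng.integers(0, 2, 4000)
    logs = draw_marker_log_totals(rng, types, cfg)
    F = log_relative_intensity(np.exp(logs))
    _, labels = fit_label_gmm(F, seed=0)
    assert (labels == LABEL_UNUSED).mean() < 0.05


def test_type_fraction_within_binomial_error():
    cfg = small_cfg(cells_per_field=60, field_shape=(1800, 1800),
                    type_fraction=0.5, n_dishes=2, fields_per_dish=2)
    fields = generate_experiment(cfg)
    cells = np.concatenate([t.cells.true_type.to_numpy() for _, t in fields])
    frac = (cells == TYPE_PROB).mean()
    n = len(cells)
    assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)


def test_null_config_types_identical_in_nonmarker_channels():
    """With all image effects at 0 the per-type area distributions match
    and the ph-channel within-cell statistics are exchangeable."""
    cfg = null_config(n_dishes=1, fields_per_dish=1, field_shape=(1600, 1600),
                      cells_per_field=40, touching_fraction=0.0,
                      placement_margin_px=40, seed=2)
    img, truth = generate_field(cfg, 1, 1, np.random.SeedSequence(7))
    ph = img.plane("ph").astype(float)
    stats = {0: [], 1: []}
    for i, row in truth.cells.iterrows():
        own = truth.label_mask == i + 1
        stats[int(row.true_type == TYPE_PROB)].append(
            (row.area_px, ph[own].std()))
    a = np.array(stats[0])
    b = np.array(stats[1])
    # same configured distribution: means within a few standard errors
    for col in (0, 1):
        se = np.sqrt(a[:, col].var() / len(a) + b[:, col].var() / len(b))
        assert abs(a[:, col].mean() - b[:, col].mean()) < 4 * se + 1e-9


def test_touching_pairs_overlap_and_singletons_do_not():
    cfg = small_cfg(cells_per_field=20, field_shape=(1100, 1100),
                    touching_fraction=0.4, seed=13)
    img, truth = generate_field(cfg, 1, 1, np.random.SeedSequence(5))
    cells = truth.cells
    n_paired = (cells.pair_partner >= 0).sum()
    assert n_paired >= 2
    comp, n = ndi.label(truth.label_mask > 0,
                        ndi.generate_binary_structure(2, 2))
    # each touching pair merges into one component
    assert n == len(cells) - n_paired // 2


def test_focal_planes_blur_offcenter():
    cfg = small_cfg(cells_per_field=6, n_focal_planes=3, seed=17)
    img, _ = generate_field(cfg, 1, 1, np.random.SeedSequence(11))
    assert len(img.focal_offsets_um) == 3
    ref = img.plane("ph")  # in-focus
    off = img.channels["ph"][0, 0]  # most negative offset
    # defocus removes high-frequency energy
    def hf(a):
        d = np.diff(a.astype(float), axis=1)
        return np.mean(d * d)
    assert hf(off) < 0.9 * hf(ref)


def test_time_planes_share_scene_but_not_noise():
    cfg = small_cfg(cells_per_field=6, n_time_planes=2, seed=19)
    img, _ = generate_field(cfg, 1, 1, np.random.SeedSequence(13))
    t0 = img.channels["ph"][0, 0].astype(float)
    t1 = img.channels["ph"][0, 1].astype(float)
    assert not np.array_equal(t0, t1)
    diff = t0 - t1
    assert abs(diff.mean()) < 1.0           # same underlying scene
    assert diff.std() < 3 * cfg.noise_sd    # differs only by sensor noise


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(type_fraction=1.5).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(size_sd=-1).validate()
    with pytest.raises(ValueError):
        # field far too small for the configured cell size
        generate_field(SyntheticConfig(field_shape=(60, 60)), 1, 1,
                       np.random.SeedSequence(0))
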