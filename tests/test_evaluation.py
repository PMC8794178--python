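"""AUC oracle checks and dish-level cross-validation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellchannel.evaluation import (
    ChannelConfig,
    build_input_stack,
    compute_auc,
    crossvalidate,
    paired_permutation_pvalue,
    permutation_null_mean_auc,
    run_grid,
    summarize_grid,
)


def auc_pair_counting(scores, truth):
    """O(n^2) oracle: count positive-negative pairs, ties half."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_auc_perfectly_ordered():
    assert compute_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
    assert compute_auc([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1]) == 0.0


def test_auc_all_ties_is_half():
    assert compute_auc([5.0] * 10, [0, 1] * 5) == 0.5


def test_auc_single_class_raises():
    with pytest.raises(ValueError):
        compute_auc([1, 2], [1, 1])


@pytest.mark.parametrize("seed", range(20))
def test_auc_equals_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 200))
    # heavy ties in half the cases
    if seed % 2:
        scores = rng.integers(0, 5, n).astype(float)
    else:
        scores = rng.standard_normal(n)
    truth = rng.integers(0, 2, n)
    if truth.min() == truth.max():
        truth[0] = 1 - truth[0]
    assert compute_auc(scores, truth) == pytest.approx(
        auc_pair_counting(scores, truth))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 6), st.booleans()),
                min_size=4, max_size=60).filter(
    lambda v: len({t for _, t in v}) == 2))
def test_auc_pair_counting_property(pairs):
    scores = np.array([s for s, _ in pairs], float)
    truth = np.array([t for _, t in pairs])
    assert compute_auc(scores, truth) == pytest.approx(
        auc_pair_counting(scores, truth))


def test_channel_config_rejects_marker():
    with pytest.raises(ValueError):
        ChannelConfig.single("marker")
    with pytest.raises(ValueError):
        ChannelConfig(name="x", planes=(("marker_flat", 0, 0),))
    cfg = ChannelConfig.combo(["dic", "bf", "ph"])
    assert cfg.n_channels == 3


def test_crossvalidation_one_split_per_dish(strong_pipeline):
    _, records, _, balanced = strong_pipeline
    res = crossvalidate(records, balanced, classifier="svm_size")
    assert [v["test_dish"] for v in res.validations] == [1, 2, 3]
    for v in res.validations:
        assert 0.0 <= v["auc"] <= 1.0
        assert v["n_train"] + v["n_test"] == balanced.n_total()
    # every balanced (dish, type) group contributes the same count
    counts = {k: len(v) for k, v in balanced.cells.items()}
    assert len(set(counts.values())) == 1


def test_svm_beats_chance_on_size_effect(strong_pipeline):
    """The configured size difference is detectable from area alone."""
    _, records, _, balanced = strong_pipeline
    res = crossvalidate(records, balanced, classifier="svm_size")
    assert res.mean_auc > 0.8


def test_permutation_null_centered_at_half(strong_pipeline):
    _, records, _, balanced = strong_pipeline
    res = crossvalidate(records, balanced, classifier="svm_size")
    null = permutation_null_mean_auc(res, n_perm=500, seed=0)
    assert abs(null.mean() - 0.5) < 0.02
    lo, hi = np.quantile(null, [0.005, 0.995])
    assert lo < 0.5 < hi
    # the strong-effect AUC itself lies far outside its own null band
    assert res.mean_auc > hi


def test_paired_permutation_pvalue_behaviour():
    # 8 paired values: a consistent shift is detectable (min p = 2/2^8),
    # identical inputs give p = 1
    a = np.array([0.90, 0.92, 0.91, 0.89, 0.93, 0.90, 0.91, 0.92])
    assert paired_permutation_pvalue(a, a + 0.2, seed=0) < 0.05
    assert paired_permutation_pvalue(a, a, seed=0) == pytest.approx(1.0)


def test_run_grid_bookkeeping(strong_pipeline):
    _, records, _, balanced = strong_pipeline
    plan = [{"name": "size_svm", "kind": "svm_size"},
            {"name": "size_svm_2", "kind": "svm_size"}]
    table, results = run_grid(records, balanced, plan)
    assert len(table) == 2 * 3  # configurations x dishes
    assert set(table.configuration) == {"size_svm", "size_svm_2"}
    summary = summarize_grid(table)
    assert set(summary.configuration) == {"size_svm", "size_svm_2"}
    assert (summary.between_dish_sd >= 0).all()


def test_zstack_and_timestack_inputs_build_correctly():
    """Focal and time planes become extra classifier channels; the CNN
    widths double for any multi-plane stack."""
    from cellchannel.classifiers import CNNSpec
    from cellchannel.cropping import crop_field
    from cellchannel.segmentation import segment_field
    from cellchannel.synthetic import SyntheticConfig, generate_experiment

    cfg = SyntheticConfig(n_dishes=1, fields_per_dish=1,
                          field_shape=(768, 768), cells_per_field=6,
                          touching_fraction=0.0, placement_margin_px=80,
                          n_focal_planes=3, n_time_planes=2, seed=61)
    img, _ = generate_experiment(cfg)[0]
    records = crop_field(img, segment_field(img.plane("ph", focal=1)),
                         flatten_marker=False)
    assert records
    for rec in records:
        planes = {k for k in rec.crops if k[0] == "dic"}
        assert planes == {("dic", f, t) for f in range(3) for t in range(2)}
    zstack = ChannelConfig(name="dic_z3",
                           planes=(("dic", 0, 0), ("dic", 1, 0), ("dic", 2, 0)))
    x = build_input_stack(records, zstack)
    assert x.shape == (len(records), 3, 150, 150)
    assert np.isfinite(x).all() and (x != 0).any()
    tstack = ChannelConfig(name="dic_t2",
                           planes=(("dic", 1, 0), ("dic", 1, 1)))
    assert build_input_stack(records, tstack).shape == (len(records), 2, 150, 150)
    assert CNNSpec(in_channels=zstack.n_channels).conv_widths == (32, 32, 64, 64)
    # contour-only input: binary crops survive masking + mean-1 normalisation
    contour = build_input_stack(records, ChannelConfig.single("contour"))
    assert contour.shape == (len(records), 1, 150, 150)
    assert (contour > 0).any(axis=(1, 2, 3)).all()
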