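"""Splits, thresholded IoU, training loop and percentage-difference reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echo2vox.epivox import NetworkSpec, build_model
from echo2vox.trainkit import (
    EvalReport,
    IoUResult,
    SplitSpec,
    TrainConfig,
    evaluate,
    pct_diff_report,
    split_dataset,
    threshold_iou,
    train,
)
from oracles import set_iou

# -- splitting ---------------------------------------------------------------


@pytest.mark.parametrize(
    "n,expected",
    [(1000, (700, 150, 150)), (20, (14, 3, 3)), (10, (7, 1, 2))],
)
def test_split_sizes_floor_floor_remainder(n, expected):
    tr, va, te = split_dataset(list(range(n)), SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == expected


def test_split_reproducible_and_duplicates_rejected():
    ids = [f"m{i}" for i in range(37)]
    s1 = split_dataset(ids, SplitSpec(seed=5))
    s2 = split_dataset(ids, SplitSpec(seed=5))
    assert s1 == s2
    assert s1 != split_dataset(ids, SplitSpec(seed=6))
    with pytest.raises(ValueError):
        split_dataset(["a", "a", "b"], SplitSpec(seed=0))


@settings(max_examples=50, derandomize=True)
@given(n=st.integers(min_value=3, max_value=500), seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_split_is_partition(n, seed):
    ids = list(range(n))
    tr, va, te = split_dataset(ids, SplitSpec(seed=seed))
    assert sorted(tr + va + te) == ids
    assert not (set(tr) & set(va)) and not (set(tr) & set(te)) and not (set(va) & set(te))


def test_invalid_ratios_rejected():
    with pytest.raises(ValueError):
        SplitSpec(ratios=(0.5, 0.5, 0.1)).validate()


# -- thresholded IoU ---------------------------------------------------------


def test_iou_identity_disjoint_and_constant_pred():
    gt = (np.random.default_rng(0).random((8, 8, 8)) > 0.5).astype(np.uint8)
    assert threshold_iou(gt.astype(float), gt, 0.5).iou == 1.0
    pred = np.zeros((8, 8, 8))
    pred[:4] = 1.0
    gt2 = np.zeros((8, 8, 8), dtype=np.uint8)
    gt2[4:] = 1
    assert threshold_iou(pred, gt2, 0.5).iou == 0.0
    # constant 0.4 prediction above t=0.3 covers everything; gt covers half
    assert threshold_iou(np.full((8, 8, 8), 0.4), pred.astype(np.uint8), 0.3).iou == 0.5


def test_iou_both_empty_defined_as_one():
    empty = np.zeros((4, 4, 4))
    assert threshold_iou(empty, empty.astype(np.uint8), 0.5).iou == 1.0


def test_iou_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        threshold_iou(np.zeros((4, 4, 4)), np.zeros((8, 8, 8)), 0.5)


def test_iou_matches_set_oracle_on_random_grids():
    """100 random 8-cube grids against an explicit coordinate-set computation."""
    rng = np.random.default_rng(12)
    for _ in range(100):
        pred = rng.random((8, 8, 8))
        gt = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        t = float(rng.uniform(0.1, 0.9))
        res = threshold_iou(pred, gt, t)
        assert res.iou == pytest.approx(set_iou(pred > t, gt > 0), abs=1e-12)
        assert res.union_count >= res.intersection_count >= 0


# -- percentage-difference report --------------------------------------------


def test_pct_diff_printed_table_cells():
    """Worked examples from the published fast/accurate comparison rows."""
    fast_base = [0.645, 0.669, 0.682, 0.690]
    fast_var = [0.641, 0.663, 0.675, 0.682]
    pct, undef = pct_diff_report(fast_base, fast_var)
    assert not undef.any()
    # the printed row mixes precisions: three cells at 3 decimals, one at 2
    assert [round(x, 3) for x in pct[:3]] == [-0.620, -0.897, -1.026]
    assert round(pct[3], 2) == -1.16
    acc_base = [0.670, 0.695, 0.708, 0.715]
    acc_var = [0.6687, 0.6836, 0.6949, 0.701]
    pct2, _ = pct_diff_report(acc_base, acc_var, decimals=2)
    assert pct2.tolist() == [-0.19, -1.64, -1.85, -1.96]


def test_pct_diff_zero_baseline_flagged_and_identity():
    pct, undef = pct_diff_report([0.0, 0.5], [0.1, 0.5])
    assert undef.tolist() == [True, False]
    assert np.isnan(pct[0]) and pct[1] == 0.0


# -- training loop -----------------------------------------------------------


def _tiny_model(max_views=1, seed=0):
    return build_model(
        NetworkSpec(tier="fast", variant="efficient", input_size_px=32, output_dim=16, base_width=4, max_views=max_views, seed=seed)
    )


def _one_sample(seed=0):
    rng = np.random.default_rng(seed)
    views = rng.random((1, 32, 32))
    gt = np.zeros((16, 16, 16), dtype=np.uint8)
    gt[4:12, 4:12, 4:12] = 1
    return views, gt


def test_training_overfits_single_sample():
    model = _tiny_model()
    cfg = TrainConfig(epochs=50, batch_size=1, seed=0)
    history = train(model, [_one_sample()], cfg)
    assert len(history["loss"]) == 50
    assert history["loss"][-1] < history["loss"][0]


def test_training_deterministic_given_seed():
    cfg = TrainConfig(epochs=3, batch_size=1, seed=1)
    h1 = train(_tiny_model(seed=5), [_one_sample()], cfg)
    h2 = train(_tiny_model(seed=5), [_one_sample()], cfg)
    assert h1["loss"] == h2["loss"]


def test_training_rejects_empty_and_overcapacity():
    with pytest.raises(ValueError):
        train(_tiny_model(), [], TrainConfig(epochs=1))
    views, gt = _one_sample()
    too_many = (np.repeat(views, 3, axis=0), gt)
    with pytest.raises(ValueError):
        train(_tiny_model(max_views=1), [too_many], TrainConfig(epochs=1))


# -- evaluation --------------------------------------------------------------


class _StubPerfect:
    def __init__(self, gt):
        self.gt = gt

    def __call__(self, views):
        return self.gt[None].astype(float)


class _StubZero:
    def __call__(self, views):
        return np.zeros((1, 16, 16, 16))


def test_evaluate_perfect_and_zero_predictors():
    _, gt = _one_sample()
    data = [(np.zeros((1, 32, 32)), gt)]
    perfect = evaluate(_StubPerfect(gt), data)
    assert perfect.peak_iou == 1.0
    zero = evaluate(_StubZero(), data)
    assert zero.peak_iou == 0.0
    assert np.all(zero.per_sample == 0.0)


def test_evaluate_deterministic(small_mesh):
    model = _tiny_model()
    data = [_one_sample(i) for i in range(3)]
    r1 = evaluate(model, data)
    r2 = evaluate(model, data)
    assert np.array_equal(r1.per_sample, r2.per_sample)
    assert r1.peak_iou == r2.peak_iou
    with pytest.raises(ValueError):
        evaluate(model, [])
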