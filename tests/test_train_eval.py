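import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from skelseg import (
    ExperimentGrid,
    TrainingOrder,
    compute_metrics,
    confusion_counts,
    dice_metrics,
    iou_metrics,
    is_convergent,
    predict_dataset,
    run_grid,
    train_model,
)
from skelseg.dataset import SliceDataset, SplitRole
from skelseg.train_eval import ConfusionCounts, select_best
from skelseg.unet import UNetSpec

counts_strategy = st.tuples(
    st.integers(0, 10**6), st.integers(0, 10**6), st.integers(0, 10**6), st.integers(0, 10**6)
).map(lambda t: ConfusionCounts(*t))


# -------------------------------------------------------------------- confusion


def test_confusion_perfect_prediction():
    ones = np.ones((4, 4, 4), dtype=np.uint8)
    assert confusion_counts(ones, ones) == (64, 0, 0, 0)


def test_confusion_all_missed():
    zeros = np.zeros((4, 4, 4), dtype=np.uint8)
    ones = np.ones_like(zeros)
    assert confusion_counts(zeros, ones) == (0, 0, 0, 64)


def test_confusion_matches_per_pixel_loop_oracle():
    rng = np.random.default_rng(0)
    pred = (rng.random((3, 8, 8)) > 0.5).astype(np.uint8)
    truth = (rng.random((3, 8, 8)) > 0.5).astype(np.uint8)
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif not p and not t:
            tn += 1
        elif p and not t:
            fp += 1
        else:
            fn += 1
    assert confusion_counts(pred, truth) == (tp, tn, fp, fn)
    counts = confusion_counts(pred, truth)
    assert sum(counts) == pred.size


def test_confusion_rejects_shape_mismatch_and_nonbinary():
    with pytest.raises(ValueError):
        confusion_counts(np.zeros((2, 4, 4)), np.zeros((2, 4, 5)))
    with pytest.raises(ValueError):
        confusion_counts(np.full((1, 2, 2), 2), np.zeros((1, 2, 2)))


# ---------------------------------------------------------------------- metrics


def test_iou_and_dice_hand_values():
    counts = ConfusionCounts(tp=8, tn=100, fp=1, fn=1)
    iou = iou_metrics(counts)
    assert iou.iou_mask == pytest.approx(0.8)
    assert iou.iou_background == pytest.approx(100 / 102)
    dice = dice_metrics(counts)
    assert dice.dice_mask == pytest.approx(16 / 18)
    assert dice.dice_mean == pytest.approx((16 / 18 + 200 / 202) / 2)


def test_perfect_prediction_scores_one_everywhere():
    m = compute_metrics(np.ones((2, 4, 4), np.uint8), np.ones((2, 4, 4), np.uint8))
    assert (
        m.iou_mask == m.iou_background == m.iou_mean
        == m.dice_mask == m.dice_background == m.dice_mean == 1.0
    )


def test_degenerate_empty_mask_sentinels():
    counts = ConfusionCounts(tp=0, tn=50, fp=0, fn=0)
    iou = iou_metrics(counts)
    assert iou.iou_mask == 1.0  # vacuous agreement
    assert iou.iou_background == 1.0
    # empty truth but non-empty prediction: naturally 0
    counts2 = ConfusionCounts(tp=0, tn=40, fp=10, fn=0)
    assert iou_metrics(counts2).iou_mask == 0.0


@given(counts_strategy)
def test_dice_dominates_iou_and_satisfies_identity(counts):
    iou = iou_metrics(counts)
    dice = dice_metrics(counts)
    assert dice.dice_mask >= iou.iou_mask
    assert dice.dice_background >= iou.iou_background
    if counts.tp + counts.fp + counts.fn > 0:
        assert dice.dice_mask == pytest.approx(
            2 * iou.iou_mask / (1 + iou.iou_mask)
        )


def test_six_indices_match_brute_force_on_random_pairs():
    rng = np.random.default_rng(7)
    for _ in range(20):
        pred = (rng.random((1, 8, 8)) > rng.random()).astype(np.uint8)
        truth = (rng.random((1, 8, 8)) > rng.random()).astype(np.uint8)
        m = compute_metrics(pred, truth)
        p, t = pred.astype(bool), truth.astype(bool)
        tp = int((p & t).sum()); tn = int((~p & ~t).sum())
        fp = int((p & ~t).sum()); fn = int((~p & t).sum())

        def safe(n, d):
            return n / d if d else 1.0

        assert m.iou_mask == pytest.approx(safe(tp, tp + fp + fn))
        assert m.iou_background == pytest.approx(safe(tn, tn + fp + fn))
        assert m.dice_mask == pytest.approx(safe(2 * tp, 2 * tp + fp + fn))
        assert m.dice_background == pytest.approx(safe(2 * tn, 2 * tn + fp + fn))
        assert m.iou_mean == pytest.approx((m.iou_mask + m.iou_background) / 2)
        assert m.dice_mean == pytest.approx((m.dice_mask + m.dice_background) / 2)


def test_is_convergent():
    assert not is_convergent(np.zeros((2, 4, 4), np.uint8))
    single = np.zeros((2, 4, 4), np.uint8)
    single[1, 2, 3] = 1
    assert is_convergent(single)


# --------------------------------------------------------------------- training


def _toy_dataset(n_slices=20, n_sets=5, seed=0, size=32):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 256, size=(n_slices, size, size))
    y = (x > 200).astype(np.uint8)
    per = n_slices // n_sets
    sets = [
        (x[i * per : (i + 1) * per], y[i * per : (i + 1) * per]) for i in range(n_sets)
    ]
    from skelseg.dataset import SliceRef

    refs = [SliceRef("T", i) for i in range(n_slices)]
    return SliceDataset(
        ordered_refs=refs, sets=sets, set_sizes=[per] * n_sets,
        split_role=SplitRole.TRAIN, seed=seed,
    )


def test_one_epoch_decreases_loss_in_most_seeds():
    ds = _toy_dataset()
    order = TrainingOrder((1, 2, 3, 4, 5), 1)
    improved = 0
    for seed in (1, 2, 3):
        _, hist = train_model(
            UNetSpec(2, (32, 32)), ds, order, epochs=1, seed=seed, batch_size=2
        )
        if hist[-1]["loss"] < hist[0]["loss"]:
            improved += 1
    assert improved >= 2


def test_training_order_changes_history():
    ds = _toy_dataset()
    _, fwd = train_model(
        UNetSpec(2, (32, 32)), ds, TrainingOrder((1, 2, 3, 4, 5), 1), 1, seed=0
    )
    _, rev = train_model(
        UNetSpec(2, (32, 32)), ds, TrainingOrder((5, 4, 3, 2, 1), 2), 1, seed=0
    )
    assert [h["set_index"] for h in fwd] != [h["set_index"] for h in rev]
    assert [h["loss"] for h in fwd] != [h["loss"] for h in rev]


def test_zero_epochs_returns_untrained_model():
    ds = _toy_dataset()
    model, hist = train_model(
        UNetSpec(2, (32, 32)), ds, TrainingOrder((1, 2, 3, 4, 5), 1), epochs=0
    )
    assert hist == []
    assert model.parameter_count() > 0


def test_train_rejects_test_dataset_and_empty():
    ds = _toy_dataset()
    ds.split_role = SplitRole.TEST
    with pytest.raises(ValueError):
        train_model(UNetSpec(2, (32, 32)), ds, TrainingOrder((1, 2, 3, 4, 5), 1), 1)


# ------------------------------------------------------------------------- grid


def test_tie_break_prefers_dice_mask_then_tp():
    rows = [
        {"convergent": True, "dice_mean": 0.9, "dice_mask": 0.8, "tp": 10, "id": "a"},
        {"convergent": True, "dice_mean": 0.9, "dice_mask": 0.85, "tp": 5, "id": "b"},
        {"convergent": True, "dice_mean": 0.9, "dice_mask": 0.85, "tp": 7, "id": "c"},
        {"convergent": False, "dice_mean": 0.99, "dice_mask": 0.99, "tp": 99, "id": "d"},
    ]
    assert select_best(rows)["id"] == "c"
    assert select_best([rows[-1]]) is None


def test_toy_grid_bookkeeping():
    ds = _toy_dataset(n_slices=10, size=32)
    test = _toy_dataset(n_slices=4, n_sets=1, seed=9, size=32)
    test.split_role = SplitRole.TEST
    orders = (TrainingOrder((1, 2, 3, 4, 5), 1), TrainingOrder((2, 1, 3, 5, 4), 2))
    grid = ExperimentGrid(
        f_values=(2,), e_values=(1,), orders=orders, input_size=(32, 32)
    )
    result = run_grid(grid, ds, test, seed=0, batch_size=2)
    assert len(result.rows) == 2
    df = result.to_dataframe()
    assert {"experiment", "F", "E", "order_id", "tp", "dice_mean", "convergent"} <= set(
        df.columns
    )
    convergent_rows = [r for r in result.rows if r["convergent"]]
    if convergent_rows:
        assert result.best in result.rows
    else:
        assert result.best is None
    for row in result.rows:
        assert row["tp"] + row["tn"] + row["fp"] + row["fn"] == test.sets[0][0].size
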