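"""Train a small U-Net on phantom slices and score it on held-out patients.

Generates a 12-patient phantom cohort, preprocesses it (couch removal,
0-300 HU thresholding, Experiment-A normalization at dataset assembly),
builds the randomized five-set training dataset, trains an F=2 U-Net for
eight epochs, and prints the six pixel-wise indices on the unshuffled test
patients.
"""

import numpy as np

from skelseg import (
    PreprocessConfig,
    build_test_dataset,
    build_training_dataset,
    compute_metrics,
    is_convergent,
    make_training_orders,
    phantom_cohort,
    predict_dataset,
    run_preprocess,
    split_cohort,
    train_model,
)
from skelseg.unet import UNetSpec

cohort = phantom_cohort(12, seed=7, slice_range=(8, 12))
train_patients, test_patients = split_cohort(cohort, 0.85, seed=1)
print(f"cohort: {len(train_patients)} training / {len(test_patients)} test patients")

cfg = PreprocessConfig(normalization_mode="A")
prep_train = [(run_preprocess(ct, cfg), m) for ct, m in train_patients]
prep_test = [(run_preprocess(ct, cfg), m) for ct, m in test_patients]

train = build_training_dataset(prep_train, seed=2)
test = build_test_dataset(prep_test)
print(f"training sets: {train.set_sizes} slices, test: {test.set_sizes[0]} slices")

order = make_training_orders(1, 5, seed=3)[0]
model, history = train_model(
    UNetSpec(f_channels=2, input_size=(64, 64)), train, order, epochs=8, seed=4
)
print(f"set order {order.order}; loss {history[0]['loss']:.4f} -> {history[-1]['loss']:.4f}")

pred = predict_dataset(model, test)
truth = np.concatenate([out for _, out in test.sets])
m = compute_metrics(pred, truth)
print(f"convergent: {is_convergent(pred)}")
print(f"IoU  (mask/background/mean): {m.iou_mask:.3f} / {m.iou_background:.3f} / {m.iou_mean:.3f}")
print(f"Dice (mask/background/mean): {m.dice_mask:.3f} / {m.dice_background:.3f} / {m.dice_mean:.3f}")
# Dice(mask) is the fraction-overlap of predicted and true skeleton;
# values near 1 mean the net recovered the cortical+marrow geometry.
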