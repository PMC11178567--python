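"""The evaluation protocol on hand-made predictions.

Demonstrates the dice convention (absent/absent scores 1), the two-level
average, the pixelwise confusion matrix, and the signed-rank comparison.
"""
import numpy as np

from implyseg import (
    ClassCatalog,
    build_dice_table,
    dice_binary,
    pixel_confusion,
    wilcoxon_compare,
)

catalog = ClassCatalog(("liver", "stomach"))

print("dice of two empty masks:", dice_binary(np.zeros((2, 2)), np.zeros((2, 2))))
print("dice of 1-pixel pred vs 2-pixel truth:",
      round(dice_binary(np.array([[1, 0, 0]]), np.array([[1, 1, 0]])), 4))

# two frames: one annotated for liver, one fully annotated
predictions = {
    "f0": np.array([[0, 0], [2, 2]]),  # liver on top, background below
    "f1": np.array([[0, 1], [2, 2]]),
}
ground_truth = {
    "f0": {"liver": np.array([[1, 1], [0, 0]])},
    "f1": {
        "liver": np.array([[1, 0], [0, 0]]),
        "stomach": np.array([[0, 1], [0, 0]]),
        "background": np.array([[0, 0], [1, 1]]),
    },
}
table = build_dice_table(predictions, ground_truth, catalog)
print(table.frame)
print("per-class means:", table.per_class_mean().round(3).to_dict())
print("overall mean (mean of class means):", round(table.overall_mean(), 4))

cm = pixel_confusion(predictions["f1"], np.array([[0, 1], [2, 2]]), catalog)
print(cm.counts)

res = wilcoxon_compare([0.9, 0.8, 0.95, 0.9], [0.7, 0.75, 0.8, 0.85])
print(f"pooled signed-rank p = {res.p_value:.4f} (degenerate: {res.degenerate})")
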