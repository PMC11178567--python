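"""The masked, positively weighted BCE and its three weight schemes.

Shows that fully masked pixels contribute nothing, and how the negative-to-
positive ratio and softmax-of-negated-shares schemes weight rare classes up.
"""
import numpy as np

from implyseg import (
    BinarySampleAnnotation,
    ClassCatalog,
    ClassWeights,
    imply_from_binary,
    masked_weighted_bce,
    pos_weight_neg_pos_ratio,
    pos_weight_softmax_negated,
)

catalog = ClassCatalog(("liver", "stomach"))
mask = np.zeros((4, 4), dtype=np.uint8)
mask[:2, :2] = 1  # liver covers 25% of the frame
target = imply_from_binary(
    BinarySampleAnnotation("frame_000", "liver", mask), catalog
)

logits = np.zeros((2, 4, 4))  # an undecided model: sigmoid(0) = 0.5 everywhere
weights = ClassWeights({"liver": 1.0, "stomach": 1.0})
out = masked_weighted_bce([logits], [target], weights, catalog)
print(f"per-class loss: { {k: round(v, 4) for k, v in out.per_class.items()} }")
print(f"terms entering the loss: {out.term_counts}")
# liver: all 16 pixels, loss ln(2) ~ 0.6931.  stomach: only the 4 implied
# negatives count; an undecided model pays ln(2) on those too.

ratio = pos_weight_neg_pos_ratio([target], catalog, include_implied=True)
print(f"neg/pos ratio weights: { {k: round(v, 2) for k, v in ratio.weights.items()} }")
# liver is 25% positive -> weight 12/4 = 3

softmax = pos_weight_softmax_negated({"liver": 0.25, "stomach": 0.05, "background": 0.70})
print(f"softmax-negated weights: { {k: round(v, 3) for k, v in softmax.weights.items()} }")
# weights sum to 1 and shrink as a class's share of the data grows
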