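"""Rank features with fuzzy-MRMR and pick the optimal subset size.

Uses a table with two planted complementary informative columns among 48
noise columns: ranking should surface the planted pair first and forward
selection should stop at exactly two features.
"""

import numpy as np

import tumortex as tx
from tumortex.selection import fmrmr_rank, forward_select

X, y, planted = tx.planted_feature_table(seed=5)
print(f"table: {X.shape[0]} samples x {X.shape[1]} features; "
      f"planted columns {planted}")

ranked = fmrmr_rank(X, y)
print("top 5 ranked columns:", list(ranked.order[:5]))
print("criterion J at those steps:", np.round(ranked.criteria[:5], 3))

res = forward_select(ranked, X, y)
print(f"optimal subset size O = {res.O}; selected columns {sorted(res.subset)}")
print("LOO error trace e_1..e_5:", np.round(res.error_trace[:5], 3))
# J drops sharply after the informative pair (relevance ~0 minus a
# redundancy penalty for noise columns); the error trace shows e_1 > 0
# (each planted feature is blind on three patients) and e_2 = 0.
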