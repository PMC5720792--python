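"""Cross-validated naive-Bayes survival classification, per feature family.

Builds a synthetic study cohort (20 vs 15), extracts all 255 features, and
evaluates leave-one-image-out CV with fuzzy-MRMR selection nested in every
training fold, for the edge-based ACM2 family, the intensity histogram,
and all features combined.
"""

import warnings

import tumortex as tx

warnings.filterwarnings("ignore")

cohort = tx.generate_cohort(tx.SyntheticCohortSpec(seed=11))
table = tx.build_cohort_table(cohort)
print(f"feature table: {table.features.shape[0]} patients x "
      f"{table.features.shape[1]} features")

for family in ("acm2", "ih", "all"):
    r = tx.loo_cv(table, family=family)
    print(f"{family:>5}: AUC={r.auc:.3f}  Ac={100 * r.accuracy:.2f}%  "
          f"Sn={r.sensitivity:.2f}  Sp={r.specificity:.2f}")

r3 = tx.repeated_kfold_cv(table, k=3, repeats=20, seed=11, family="acm2")
print(f"acm2, 3-fold x 20 repeats: AUC={r3.auc:.3f}  "
      f"Ac={100 * r3.accuracy:.2f}%")
# The directional-edge ACM2 family separates the synthetic survival groups
# best -- the class contrast is concentrated in gradient-orientation
# coherence -- while the intensity histogram sees only the necrosis blobs.
# Sn is the recall of long survivors, Sp of short survivors, at a 0.5
# posterior threshold.
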