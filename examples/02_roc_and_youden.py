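"""Single-modality ROC analysis: empirical curve, AUC with a bootstrap CI,
and the maximum-Youden operating point.

The Youden index J = sensitivity + specificity - 1 picks the threshold that
best balances cancer detection against false recalls.
"""

import fuseroc as fr

table = fr.generate_cohort(fr.CohortConfig(seed=0))
labels = fr.binary_labels(table)
scores = table["score_dm"].to_numpy()

curve = fr.empirical_roc(scores, labels)
point = fr.max_youden(curve)
ci = fr.bootstrap_ci(
    lambda t: fr.auc(t["score_dm"].to_numpy(), fr.binary_labels(t)),
    table,
    n_replicates=2000,
    seed=1,
)

print(f"AUC(dm) = {ci.point:.3f}  (95% CI {ci.lower:.3f}-{ci.upper:.3f})")
print(
    f"max Youden J = {point.youden_j:.3f} at threshold {point.threshold:.3f} "
    f"(sens {100 * point.sensitivity:.1f}%, spec {100 * point.specificity:.1f}%)"
)
print(f"curve has {len(curve)} operating points; export with curve.to_frame()")
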