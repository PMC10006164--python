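"""Compare F-score feature ranking and SVM AUC on original vs avatar data.

Emulates a graded 1-10 diagnostic dataset with decreasing feature effect
sizes, avatarizes it, and runs the repeated 70/30 split protocol: F-scores
computed on each training split rank the features, the top 5 feed an
RBF-kernel SVM, and the AUC is measured on the test split.
"""

from avatarize import (
    AvatarConfig,
    ClassificationBlock,
    FixtureSpec,
    classification_comparison,
    generate_avatars,
    generate_classification,
)

data = generate_classification(
    FixtureSpec(
        n=800,
        seed=5,
        classification=ClassificationBlock(effect_sizes=(3.0, 2.0, 1.0, 0.5, 0.0)),
    )
)
avatar = generate_avatars(data, AvatarConfig(k=20, seed=6)).data

for name, d in (("original", data), ("avatar  ", avatar)):
    r = classification_comparison(d, "outcome", n_repeats=25, seed=9)
    ranked = ", ".join(r["selected_rank"])
    print(f"{name}: AUC = {r['auc_mean']:.2f}% (sd {r['auc_sd']:.2f}), ranking: {ranked}")
print()
print(
    "The feature ranking should match the generating effect-size order\n"
    "(f0 > f1 > f2 > f3 > f4) on both datasets, and the AUCs should be close:\n"
    "the avatar data supports the same predictive analysis."
)
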