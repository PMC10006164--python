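"""DCR/NNDR of avatar data against the real-data-vs-itself baseline.

Draws ten 70% samples; per sample, avatars are generated from the sample
and the distance-to-closest-record (DCR) and nearest-neighbor distance
ratio (NNDR) are computed between avatars and the sample, and between the
held-out 30% and the sample (the natural "how close is real data to
itself" reference).
"""

from avatarize import (
    AvatarConfig,
    ExperimentPlan,
    FixtureSpec,
    dcr_nndr_protocol,
    generate_mixed,
)

data = generate_mixed(FixtureSpec(n=700, seed=8))
plan = ExperimentPlan(protocol="dcr_nndr", base_seed=21, config=AvatarConfig(k=20))
r = dcr_nndr_protocol(data, plan, n_samples=10)

for side, label in (("synthetic", "avatar vs sample  "),
                    ("holdout_baseline", "holdout vs sample")):
    d, n = r[side]["dcr"], r[side]["nndr"]
    print(
        f"{label}: DCR median {d['median']:.3f} (q05 {d['q05']:.3f}, q95 {d['q95']:.3f})"
        f" | NNDR median {n['median']:.3f}"
    )
print()
print(
    "Avatars drawn inside local neighborhoods sit closer to the originals\n"
    "than a fresh real sample does (lower DCR), while NNDR near 1 shows no\n"
    "avatar is isolated next to a unique original record."
)
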