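"""Stochasticity of re-identification across independent avatarizations.

Runs 25 independent k=20 avatarizations of the same dataset and counts,
per individual, in how many runs a distance-based linkage attack would
have re-identified them (local cloaking of 0).
"""

import numpy as np

from avatarize import (
    AvatarConfig,
    ExperimentPlan,
    FixtureSpec,
    generate_mixed,
    repeated_avatarization,
)

data = generate_mixed(FixtureSpec(n=400, seed=15))
plan = ExperimentPlan(
    protocol="repeat_runs", n_runs=25, base_seed=30, config=AvatarConfig(k=20)
)
r = repeated_avatarization(data, plan)
zc = r["zero_cloaking_counts"]

print(f"runs: {r['n_runs']}, individuals: {len(zc)}")
print(f"never re-identified       : {np.mean(zc == 0) * 100:.1f}%")
print(f"re-identified in >=10 runs: {np.mean(zc >= 10) * 100:.1f}%")
print(f"mean hidden rate per run  : {r['hidden_rate_per_run'].mean():.1f}%")
print()
print(
    "Whether an individual's avatar lands closest to them is a property of\n"
    "the random draw, not of the individual: almost nobody is re-identified\n"
    "consistently across runs, so an attacker cannot rely on the linkage."
)
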