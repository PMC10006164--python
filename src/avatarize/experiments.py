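"""Experiment protocols: repeated runs, k-sweep, and DCR/NNDR vs holdout.

Three seeded protocols characterize a generator's behaviour:

* ``repeated_avatarization`` — many independent runs at fixed k; for
  each individual, count the runs in which a distance-based linkage
  attack would have re-identified them (local cloaking 0).
* ``k_sweep`` — repeated runs across a grid of k values, tracking a
  utility endpoint (Cox HR or SVM AUC) and the local-cloaking
  distribution, to expose the privacy/utility trade-off in k.
* ``dcr_nndr_protocol`` — repeated 70% samples of the original data;
  per sample, DCR/NNDR between generated synthetic data and the sample,
  against the baseline of DCR/NNDR between the 30% holdout and the
  sample (how close real data is to itself).

Every run's seeds are derived from the plan's base seed with a
splittable scheme, so adding runs never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data_model import TabularDataset
from .engine import AvatarConfig, generate_avatars
from .privacy import dcr, local_cloaking, nndr
from .projection import fit_famd, transform
from .utility import classification_comparison, survival_comparison

__all__ = [
    "ExperimentPlan",
    "PlanError",
    "derive_seed",
    "repeated_avatarization",
    "k_sweep",
    "dcr_nndr_protocol",
]


class PlanError(ValueError):
    """Invalid experiment plan."""


@dataclass(frozen=True)
class ExperimentPlan:
    protocol: str = "repeat_runs"    # repeat_runs | k_sweep | dcr_nndr
    n_runs: int = 25
    k_values: tuple[int, ...] = (20,)
    sampling_fraction: float = 0.7
    base_seed: int = 0
    config: AvatarConfig = field(default_factory=AvatarConfig)

    def __post_init__(self) -> None:
        if self.protocol not in ("repeat_runs", "k_sweep", "dcr_nndr"):
            raise PlanError(f"unknown protocol {self.protocol!r}")
        if self.n_runs < 1:
            raise PlanError("n_runs must be >= 1")
        if not 0.0 < self.sampling_fraction < 1.0:
            raise PlanError("sampling_fraction must be in (0, 1)")
        if list(self.k_values) != sorted(self.k_values):
            raise PlanError("k values must be sorted ascending")


def derive_seed(base_seed: int, *key: int) -> int:
    """Splittable sub-seed: stable under adding later runs, < 2**31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _run_config(config: AvatarConfig, **overrides) -> AvatarConfig:
    return AvatarConfig(**{**config.to_dict(), **overrides})


def _cloaking_of_run(original: TabularDataset, result) -> np.ndarray:
    orig_coords = transform(result.model, original)
    avat_coords = transform(result.model, result.data)
    return local_cloaking(orig_coords, avat_coords, result.linkage)["values"]


def repeated_avatarization(original: TabularDataset, plan: ExperimentPlan) -> dict:
    """Zero-cloaking counts over ``n_runs`` independent avatarizations.

    Returns per-individual counts of runs with local cloaking 0 (the
    linkage attack succeeds), the per-run hidden rates, and the
    histogram of the counts.
    """
    if plan.protocol != "repeat_runs":
        raise PlanError("plan protocol must be 'repeat_runs'")
    n = original.n
    zero_counts = np.zeros(n, dtype=int)
    hidden_rates = []
    medians = []
    for r in range(plan.n_runs):
        cfg = _run_config(plan.config, seed=derive_seed(plan.base_seed, r, 1))
        result = generate_avatars(original, cfg)
        counts = _cloaking_of_run(original, result)
        zero_counts += counts == 0
        hidden_rates.append(100.0 * np.mean(counts >= 1))
        medians.append(float(np.median(counts)))
    hist = np.bincount(zero_counts, minlength=plan.n_runs + 1)
    return {
        "zero_cloaking_counts": zero_counts,
        "histogram": hist,
        "n_runs": plan.n_runs,
        "hidden_rate_per_run": np.asarray(hidden_rates),
        "median_cloaking_per_run": np.asarray(medians),
    }


def k_sweep(
    original: TabularDataset,
    plan: ExperimentPlan,
    endpoint: Callable[[TabularDataset], float] | None = None,
    endpoint_name: str = "endpoint",
) -> dict:
    """Utility endpoint and cloaking distribution across a k grid.

    ``endpoint`` maps a (synthetic) dataset to a scalar, e.g. a Cox HR
    or an AUC; it may be None to track privacy only.  Per k, ``n_runs``
    avatarizations are run; means and normal-approximation 95% CI bands
    are reported along with the pooled local-cloaking distribution.
    """
    if plan.protocol != "k_sweep":
        raise PlanError("plan protocol must be 'k_sweep'")
    if max(plan.k_values) > original.n - 1:
        raise PlanError("every k must be <= n - 1")
    rows = []
    for k in plan.k_values:
        vals, med_cloak, cloak_all = [], [], []
        for r in range(plan.n_runs):
            cfg = _run_config(
                plan.config, k=k, seed=derive_seed(plan.base_seed, k, r, 1)
            )
            result = generate_avatars(original, cfg)
            counts = _cloaking_of_run(original, result)
            med_cloak.append(float(np.median(counts)))
            cloak_all.append(counts)
            if endpoint is not None:
                vals.append(float(endpoint(result.data)))
        vals = np.asarray(vals)
        row = {
            "k": k,
            "median_cloaking_runs": np.asarray(med_cloak),
            "median_cloaking": float(np.median(med_cloak)),
            "cloaking_pooled": np.concatenate(cloak_all),
        }
        if endpoint is not None:
            half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            row[endpoint_name + "_mean"] = float(vals.mean())
            row[endpoint_name + "_ci"] = (float(vals.mean() - half), float(vals.mean() + half))
            row[endpoint_name + "_values"] = vals
        rows.append(row)
    return {"per_k": rows, "k_values": list(plan.k_values)}


def survival_endpoint(time_col: str, event_col: str, arm_col: str) -> Callable:
    """Endpoint factory: hazard ratio of a two-arm Cox fit."""

    def _ep(data: TabularDataset) -> float:
        return survival_comparison(data, time_col, event_col, arm_col)["hr"]

    return _ep


def auc_endpoint(outcome_col: str, n_repeats: int = 10, **kw) -> Callable:
    """Endpoint factory: mean SVM AUC (percent) over stratified splits."""

    def _ep(data: TabularDataset) -> float:
        return classification_comparison(
            data, outcome_col, n_repeats=n_repeats, **kw
        )["auc_mean"]

    return _ep


def dcr_nndr_protocol(
    original: TabularDataset,
    plan: ExperimentPlan,
    generator: Callable[[TabularDataset, int], TabularDataset] | None = None,
    n_samples: int = 10,
) -> dict:
    """Repeated-sampling DCR/NNDR audit with an original-holdout baseline.

    Draws ``n_samples`` seeded ``sampling_fraction`` samples without
    replacement.  Per sample: the generator produces synthetic data from
    the sample; DCR/NNDR are computed between synthetic and sample, and
    between the disjoint holdout and the sample, all in the projection
    space fitted on the sample.  Per-record values are pooled across
    samples; medians and (0.05, 0.95) quantiles are reported.

    ``generator(sample, seed)`` defaults to the avatar engine with the
    plan's config.
    """
    if plan.protocol != "dcr_nndr":
        raise PlanError("plan protocol must be 'dcr_nndr'")
    if generator is None:
        def generator(sample: TabularDataset, seed: int) -> TabularDataset:
            return generate_avatars(sample, _run_config(plan.config, seed=seed)).data

    n = original.n
    n_train = int(round(n * plan.sampling_fraction))
    syn_dcr, syn_nndr, base_dcr, base_nndr = [], [], [], []
    for s in range(n_samples):
        rng = np.random.default_rng(derive_seed(plan.base_seed, s, 0))
        perm = rng.permutation(n)
        train_idx, hold_idx = perm[:n_train], perm[n_train:]
        sample = original.take(train_idx)
        holdout = original.take(hold_idx)
        synth = generator(sample, derive_seed(plan.base_seed, s, 1))
        model = fit_famd(sample)
        c_sample = transform(model, sample)
        c_synth = transform(model, synth)
        c_hold = transform(model, holdout)
        syn_dcr.append(dcr(c_sample, c_synth)["values"])
        syn_nndr.append(nndr(c_sample, c_synth)["values"])
        base_dcr.append(dcr(c_sample, c_hold)["values"])
        base_nndr.append(nndr(c_sample, c_hold)["values"])

    def pool(chunks: Sequence[np.ndarray]) -> dict:
        v = np.concatenate(chunks)
        return {
            "median": float(np.median(v)),
            "q05": float(np.quantile(v, 0.05)),
            "q95": float(np.quantile(v, 0.95)),
            "values": v,
        }

    return {
        "synthetic": {"dcr": pool(syn_dcr), "nndr": pool(syn_nndr)},
        "holdout_baseline": {"dcr": pool(base_dcr), "nndr": pool(base_nndr)},
        "n_samples": n_samples,
        "sampling_fraction": plan.sampling_fraction,
    }
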