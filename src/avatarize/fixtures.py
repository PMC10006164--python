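"""Seeded generators of mixed-type datasets with known structure.

These emulate the statistical features the method's target data exhibit
— Gaussian clusters with categorical composition, exact duplicate
records, a two-arm survival outcome with a known hazard ratio, and
graded 1-10 ordinal features with a separable binary outcome — so every
stage of the pipeline is testable against ground truth without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_model import TabularDataset, VariableSpec

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "generate_mixed",
    "generate_survival",
    "generate_classification",
]


class FixtureError(ValueError):
    """Invalid fixture specification."""


@dataclass(frozen=True)
class SurvivalBlock:
    """Two-arm exponential survival outcome with a target hazard ratio."""

    hazard_ratio: float = 0.5      # arm 1 vs arm 0
    baseline_rate: float = 0.1     # events per time unit in arm 0
    censoring_rate: float = 0.2    # expected censored fraction

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise FixtureError("hazard_ratio must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise FixtureError("censoring_rate must be in [0, 1)")


@dataclass(frozen=True)
class ClassificationBlock:
    """Graded 1-10 features whose class-conditional means differ."""

    effect_sizes: tuple[float, ...] = (3.0, 2.0, 1.0, 0.5, 0.0)
    perfect_separator: bool = False
    positive_fraction: float = 0.35


@dataclass(frozen=True)
class FixtureSpec:
    n: int = 1000
    mixture_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    cluster_means: tuple[tuple[float, ...], ...] | None = None
    cluster_cov_scale: float = 1.0
    n_continuous: int = 4
    cluster_separation: float = 6.0
    categorical_levels: tuple[str, ...] = ("a", "b", "c")
    #: per-cluster level probabilities; default concentrates one level per cluster
    categorical_probs: tuple[tuple[float, ...], ...] | None = None
    duplicate_fraction: float = 0.0
    survival: SurvivalBlock | None = None
    classification: ClassificationBlock | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if w.size < 1 or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise FixtureError("mixture weights must be non-negative and sum to 1")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise FixtureError("duplicate_fraction must be in [0, 1)")


def _cluster_params(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    g = len(spec.mixture_weights)
    if spec.cluster_means is not None:
        means = np.asarray(spec.cluster_means, dtype=float)
    else:
        # clusters spread along a simplex-ish layout, pairwise separated
        rng = np.random.default_rng(12345)  # layout constant, not data draw
        means = rng.normal(size=(g, spec.n_continuous))
        means /= np.linalg.norm(means, axis=1, keepdims=True)
        means *= spec.cluster_separation
    if spec.categorical_probs is not None:
        probs = np.asarray(spec.categorical_probs, dtype=float)
    else:
        # one dominant level per cluster, remainder spread equally
        L = len(spec.categorical_levels)
        probs = np.full((g, L), 0.1 / max(L - 1, 1))
        for c in range(g):
            probs[c, c % L] = 0.9
    probs = probs / probs.sum(axis=1, keepdims=True)
    return means, probs


def generate_mixed(spec: FixtureSpec) -> TabularDataset:
    """Gaussian-mixture continuous block + per-cluster categorical column.

    Cluster labels are drawn from the mixture weights, continuous values
    from per-cluster spherical Gaussians, the categorical level from the
    per-cluster multinomial.  A ``duplicate_fraction`` of the rows are
    exact copies of earlier rows (appended, total row count = n).
    Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    means, probs = _cluster_params(spec)
    cov = spec.cluster_cov_scale
    if cov <= 0:
        raise FixtureError("cluster_cov_scale must be > 0 (PSD covariance)")
    n_dup = int(round(spec.n * spec.duplicate_fraction))
    n_base = spec.n - n_dup
    labels = rng.choice(len(spec.mixture_weights), size=n_base, p=spec.mixture_weights)
    X = means[labels] + rng.normal(scale=np.sqrt(cov), size=(n_base, spec.n_continuous))
    L = len(spec.categorical_levels)
    cat_idx = np.array([rng.choice(L, p=probs[c]) for c in labels])
    frame = pd.DataFrame(
        {f"x{j}": X[:, j] for j in range(spec.n_continuous)}
    )
    frame["group"] = np.array(spec.categorical_levels, dtype=object)[cat_idx]
    if n_dup:
        src = rng.integers(0, n_base, size=n_dup)
        frame = pd.concat([frame, frame.iloc[src]], ignore_index=True)
    schema = [VariableSpec(f"x{j}", "continuous") for j in range(spec.n_continuous)]
    schema.append(VariableSpec("group", "categorical", tuple(spec.categorical_levels)))
    return TabularDataset(schema, frame)


def _uniform_censor_bound(rates: np.ndarray, arm_probs: np.ndarray, target: float) -> float:
    """Upper bound u of Uniform(0, u) censoring achieving the target rate.

    For T ~ Exp(rate) and C ~ Uniform(0, u), P(C < T) = (1 - e^{-rate u})/(rate u);
    the mixture over arms is solved for u by Brent root-finding.
    """

    def censored_frac(u: float) -> float:
        lam = rates * u
        return float(np.sum(arm_probs * (1 - np.exp(-lam)) / lam))

    lo, hi = 1e-9, 1e9
    if censored_frac(hi) > target:  # even huge bounds censor too much (tiny target)
        hi = 1e12
    return brentq(lambda u: censored_frac(u) - target, lo, hi, xtol=1e-12, rtol=1e-12)


def generate_survival(spec: FixtureSpec) -> TabularDataset:
    """Mixed fixture plus (time, event, arm) columns.

    Arm ~ Bernoulli(0.5); event times are exponential with the arm-1 rate
    equal to ``hazard_ratio`` times the arm-0 rate, so the true Cox HR is
    the stated value; independent Uniform(0, u) censoring with u solved to
    hit the stated expected censoring rate.
    """
    if spec.survival is None:
        raise FixtureError("spec has no survival block")
    sv = spec.survival
    base = generate_mixed(spec)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n = base.n
    arm = rng.integers(0, 2, size=n)
    rates = np.where(arm == 1, sv.baseline_rate * sv.hazard_ratio, sv.baseline_rate)
    t_event = rng.exponential(scale=1.0 / rates)
    if sv.censoring_rate > 0:
        u = _uniform_censor_bound(
            np.array([sv.baseline_rate, sv.baseline_rate * sv.hazard_ratio]),
            np.array([0.5, 0.5]),
            sv.censoring_rate,
        )
        t_cens = rng.uniform(0, u, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    frame = base.frame.copy()
    frame["time"] = time
    frame["event"] = event.astype(object).astype(str)
    frame["arm"] = arm.astype(object).astype(str)
    schema = list(base.schema) + [
        VariableSpec("time", "continuous"),
        VariableSpec("event", "boolean"),
        VariableSpec("arm", "boolean"),
    ]
    return TabularDataset(schema, frame)


def generate_classification(spec: FixtureSpec) -> TabularDataset:
    """Graded 1-10 integer features with a binary outcome.

    Feature ``f{i}`` has class-conditional mean offset ``effect_sizes[i]``
    (positive class shifted upward), Gaussian noise sd 1.5, then values
    are clipped to [1, 10] and rounded to integers to emulate ordinal
    grading.  With ``perfect_separator`` an extra feature takes values in
    disjoint ranges per class (AUC 1 achievable).
    """
    if spec.classification is None:
        raise FixtureError("spec has no classification block")
    cb = spec.classification
    rng = np.random.default_rng(spec.seed + 2_000_003)
    n = spec.n
    y = (rng.random(n) < cb.positive_fraction).astype(int)
    cols: dict[str, np.ndarray] = {}
    for i, d in enumerate(cb.effect_sizes):
        base_mean = 3.5
        x = rng.normal(loc=base_mean + d * y, scale=1.5, size=n)
        cols[f"f{i}"] = np.clip(np.rint(x), 1, 10)
    if cb.perfect_separator:
        lo = rng.integers(1, 5, size=n)   # negative class range [1, 4]
        hi = rng.integers(6, 11, size=n)  # positive class range [6, 10]
        cols["sep"] = np.where(y == 1, hi, lo).astype(float)
    frame = pd.DataFrame(cols)
    frame["outcome"] = np.where(y == 1, "malignant", "benign")
    schema = [VariableSpec(c, "continuous") for c in cols]
    schema.append(VariableSpec("outcome", "categorical", ("benign", "malignant")))
    return TabularDataset(schema, frame)
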