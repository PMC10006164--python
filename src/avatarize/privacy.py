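"""Distance-based privacy metrics for synthetic tabular data.

Two generic metrics apply to any generator: the distance to the closest
record (DCR, per synthetic record the Euclidean distance to its nearest
real record) and the nearest neighbor distance ratio (NNDR, the ratio
of nearest to second-nearest real-record distances, in [0, 1]).  Two
metrics exploit the one-avatar-per-record structure and quantify a
distance-based linkage attack: *local cloaking* counts, for each
original record, how many avatars are strictly closer to it than its
own avatar (0 means the attack links correctly), and the *hidden rate*
is the percentage of records with local cloaking >= 1, i.e. the
probability the attack is wrong.

All distances are computed in the full-rank projection space fitted on
the original data (synthetic data placed into it via ``transform``);
the space used is recorded in the report.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import TabularDataset
from .projection import ProjectionModel, transform

__all__ = [
    "dcr",
    "nndr",
    "local_cloaking",
    "hidden_rate",
    "privacy_report",
    "MetricError",
]


class MetricError(ValueError):
    """Invalid input to a privacy metric."""


def _summary(values: np.ndarray) -> dict:
    return {
        "median": float(np.median(values)),
        "q05": float(np.quantile(values, 0.05)),
        "q95": float(np.quantile(values, 0.95)),
    }


def dcr(real_coords: np.ndarray, synth_coords: np.ndarray) -> dict:
    """Distance to closest record for every synthetic row.

    Returns ``{"values": per-record distances, "median", "q05", "q95"}``.
    """
    real = np.asarray(real_coords, dtype=float)
    synth = np.asarray(synth_coords, dtype=float)
    if real.size == 0 or real.shape[0] == 0:
        raise MetricError("empty real coordinate set")
    d = cdist(synth, real).min(axis=1)
    return {"values": d, **_summary(d)}


def nndr(real_coords: np.ndarray, synth_coords: np.ndarray) -> dict:
    """Nearest neighbor distance ratio d1/d2 for every synthetic row.

    d1 <= d2 are the two smallest synthetic-to-real distances; when
    d2 = 0 (the synthetic point coincides with duplicated real points)
    the ratio is defined as 1, the maximally non-isolated value.
    """
    real = np.asarray(real_coords, dtype=float)
    synth = np.asarray(synth_coords, dtype=float)
    if real.shape[0] < 2:
        raise MetricError("NNDR needs at least 2 real records")
    d = cdist(synth, real)
    two = np.partition(d, 1, axis=1)[:, :2]
    d1 = two.min(axis=1)
    d2 = two.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(d2 > 0, d1 / np.where(d2 > 0, d2, 1.0), 1.0)
    return {"values": r, **_summary(r)}


def local_cloaking(
    original_coords: np.ndarray,
    avatar_coords: np.ndarray,
    linkage: np.ndarray,
) -> dict:
    """Per-original-row count of avatars strictly closer than the own avatar.

    ``linkage[i]`` is the avatar row generated from original row ``i``.
    Ties do not count as closer (conservative for the attacker).
    Returns ``{"values": counts, "median"}``.
    """
    orig = np.asarray(original_coords, dtype=float)
    avat = np.asarray(avatar_coords, dtype=float)
    linkage = np.asarray(linkage, dtype=int)
    n = orig.shape[0]
    if linkage.shape != (n,) or sorted(linkage.tolist()) != list(range(avat.shape[0])):
        raise MetricError("linkage is not a bijection between originals and avatars")
    d = cdist(orig, avat)
    own = d[np.arange(n), linkage]
    counts = (d < own[:, None]).sum(axis=1)
    # the own avatar can never be strictly closer than itself, no correction
    return {"values": counts.astype(int), "median": float(np.median(counts))}


def hidden_rate(local_cloaking_counts: np.ndarray) -> float:
    """Percentage of original rows whose avatar is not their closest avatar.

    Strict-inequality convention: a tie with the own avatar does not hide
    the individual.
    """
    counts = np.asarray(local_cloaking_counts)
    if counts.size == 0:
        raise MetricError("empty local cloaking vector")
    return float(100.0 * np.mean(counts >= 1))


def privacy_report(
    original: TabularDataset,
    avatar_result,
    model: ProjectionModel | None = None,
) -> dict:
    """Full privacy audit of one avatarization in its declared space."""
    model = model or avatar_result.model
    orig_coords = transform(model, original)
    avat_coords = transform(model, avatar_result.data)
    lc = local_cloaking(orig_coords, avat_coords, avatar_result.linkage)
    dc = dcr(orig_coords, avat_coords)
    nn = nndr(orig_coords, avat_coords)
    return {
        "space": {
            "ncomp": model.ncomp,
            "distance": avatar_result.config.distance,
            "note": "full-rank FAMD space fitted on the original data",
        },
        "dcr": {k: (v.tolist() if k == "values" else v) for k, v in dc.items()},
        "nndr": {k: (v.tolist() if k == "values" else v) for k, v in nn.items()},
        "local_cloaking": {
            "values": lc["values"].tolist(),
            "median": lc["median"],
        },
        "hidden_rate": hidden_rate(lc["values"]),
    }
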