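"""Core avatar generator: local KNN model, stochastic weights, weighted center.

For each original record ``O`` the generator finds its k nearest
neighbors (self excluded) in the first ``nd`` components of the FAMD
space, gives neighbor ``i`` a raw weight

    P_i = D_i * R_i * C_i

with ``D_i`` the inverse of the distance to the neighbor, ``R_i`` an
Exponential(lambda) draw and ``C_i = (1/2)^j`` where ``j`` runs over a
uniformly shuffled ``[1..k]``, normalizes the weights to sum to one, and
places the avatar at the weighted center of the neighbors' *full-rank*
coordinates.  Averaging in full rank keeps the inverse transform exact;
only the neighbor search is dimension-reduced.  The avatar table is
finally row-shuffled to break the positional link to the originals; the
pre-shuffle linkage is retained in memory for privacy metrics only and
is never written to disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import __version__
from .data_model import TabularDataset, read_dataset, write_dataset
from .projection import ProjectionModel, fit_famd, inverse_transform, transform

__all__ = [
    "AvatarConfig",
    "NeighborModel",
    "AvatarDataset",
    "ConfigError",
    "find_neighbors",
    "draw_weights",
    "generate_avatars",
    "avatarize",
]


class ConfigError(ValueError):
    """Invalid generation configuration."""


@dataclass(frozen=True)
class AvatarConfig:
    """Parameters controlling one avatarization run.

    ``k`` sets the local model size (privacy/utility trade-off knob),
    ``nd`` how many leading components the neighbor search uses
    (``None`` = smallest count reaching 90% cumulative variance),
    ``distance`` the metric in that reduced space ("mahalanobis" is
    Euclidean on variance-standardized component scores, which is the
    Mahalanobis distance in an orthogonal factor basis),
    ``contribution_law`` whether neighbor contributions follow the
    halving sequence (1/2)^j or are equal, and ``exponential_rate`` the
    rate lambda of the random factor R_i.
    """

    k: int = 20
    nd: int | None = None
    distance: str = "euclidean"
    contribution_law: str = "halving"
    exponential_rate: float = 1.0
    column_weights: dict[str, float] = field(default_factory=dict)
    perturbation_level: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.nd is not None and self.nd < 1:
            raise ConfigError("nd must be >= 1")
        if self.distance not in ("euclidean", "mahalanobis"):
            raise ConfigError(f"unknown distance {self.distance!r}")
        if self.contribution_law not in ("halving", "equal"):
            raise ConfigError(f"unknown contribution_law {self.contribution_law!r}")
        if self.exponential_rate <= 0:
            raise ConfigError("exponential_rate must be > 0")
        for name, lv in self.perturbation_level.items():
            if not 0.0 <= lv <= 1.0:
                raise ConfigError(f"perturbation_level[{name!r}] must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class NeighborModel:
    """Per-row neighborhood: indices, distances and (once drawn) weights."""

    indices: np.ndarray            # (n, k) neighbor row indices, self excluded
    distances: np.ndarray          # (n, k) non-decreasing per row
    contributions: np.ndarray | None = None  # C_i, multiset {2^-1..2^-k} per row
    random_factors: np.ndarray | None = None  # R_i draws
    raw_products: np.ndarray | None = None    # P_i = D_i R_i C_i
    weights: np.ndarray | None = None         # W_i, rows sum to 1


@dataclass
class AvatarDataset:
    """Avatar table plus the internal pre-shuffle linkage.

    ``linkage[i]`` is the row of ``data`` holding the avatar generated
    from original row ``i``; it is kept for metric computation only.
    """

    data: TabularDataset
    linkage: np.ndarray
    permutation: np.ndarray
    model: ProjectionModel
    neighbor_model: NeighborModel
    config: AvatarConfig
    coordinates_pre_shuffle: np.ndarray  # avatar full-rank coords, original order


def _search_space(model: ProjectionModel, coords: np.ndarray, config: AvatarConfig) -> np.ndarray:
    nd = config.nd if config.nd is not None else max(1, model.nd_for_variance(0.90))
    nd = min(nd, model.ncomp)
    sub = coords[:, :nd]
    if config.distance == "mahalanobis":
        sd = model.component_sd()[:nd]
        sd = np.where(sd > 0, sd, 1.0)
        sub = sub / sd
    return sub


def find_neighbors(coords: np.ndarray, config: AvatarConfig) -> NeighborModel:
    """Exact k-nearest-neighbor search over the given coordinates.

    ``coords`` must already be restricted/standardized to the search
    space (only its columns are used as-is).  Ties in distance are broken
    toward the lower row index; a row is never its own neighbor.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if config.k > n - 1:
        raise ConfigError(f"k={config.k} requires at least {config.k + 1} rows, got {n}")
    dmat = squareform(pdist(coords))
    np.fill_diagonal(dmat, np.inf)
    # stable argsort on distance gives the lower-index tie-break for free
    order = np.argsort(dmat, axis=1, kind="stable")[:, : config.k]
    dists = np.take_along_axis(dmat, order, axis=1)
    return NeighborModel(indices=order, distances=dists)


def draw_weights(
    distances: np.ndarray,
    config: AvatarConfig,
    rng: np.random.Generator,
    zero_floor: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw one row's normalized neighbor weights.

    Returns ``(W, C, R, P)``.  Distances are floored at ``zero_floor``
    before inversion so exact duplicates (distance 0) get the largest
    finite inverse-distance instead of breaking Eq.-style weighting.
    Draw order is fixed (shuffle j first, then the R vector) for
    cross-platform reproducibility.
    """
    d = np.maximum(np.asarray(distances, dtype=float), zero_floor)
    if np.any(d <= 0):
        raise ConfigError("non-positive neighbor distance after flooring")
    k = d.shape[0]
    j = rng.permutation(k) + 1
    if config.contribution_law == "halving":
        c = 0.5**j
    else:
        c = np.ones(k)
    r = rng.exponential(scale=1.0 / config.exponential_rate, size=k)
    p = (1.0 / d) * r * c
    w = p / p.sum()
    return w, c, r, p


def _zero_floor(search_coords: np.ndarray, rng_free: bool = True) -> float:
    """Duplicate-distance floor: 1e-9 x median positive pairwise distance."""
    n = search_coords.shape[0]
    if n > 3000:  # median is stable on a deterministic subsample
        idx = np.linspace(0, n - 1, 3000).astype(int)
        search_coords = search_coords[idx]
    d = pdist(search_coords)
    pos = d[d > 0]
    med = float(np.median(pos)) if pos.size else 1.0
    return 1e-9 * med if med > 0 else 1e-12


def generate_avatars(original: TabularDataset, config: AvatarConfig) -> AvatarDataset:
    """Produce one avatar per original record.

    Fits the projection on ``original``, searches neighbors in the first
    ``nd`` components, draws weights row by row from a single seeded RNG
    stream, places each avatar at the weighted center of its neighbors'
    full-rank coordinates, inverse-transforms, and shuffles the output
    rows.  Deterministic for a fixed seed.
    """
    model = fit_famd(original, column_weights=config.column_weights or None)
    coords = transform(model, original)
    search = _search_space(model, coords, config)
    nm = find_neighbors(search, config)
    floor = _zero_floor(search)

    n, k = nm.indices.shape
    rng = np.random.default_rng(config.seed)
    W = np.empty((n, k))
    C = np.empty((n, k))
    R = np.empty((n, k))
    P = np.empty((n, k))
    for i in range(n):  # row-major draw order: per row, shuffle then R
        W[i], C[i], R[i], P[i] = draw_weights(nm.distances[i], config, rng, floor)
    nm.weights, nm.contributions, nm.random_factors, nm.raw_products = W, C, R, P

    avatar_coords = np.einsum("ik,ikc->ic", W, coords[nm.indices])

    if config.perturbation_level:
        # experimental: per-variable convex shrinkage toward the unweighted
        # neighbor centroid, applied in encoded space (semantics of the
        # "percentage of perturbation" parameter are not settled)
        centroid_coords = coords[nm.indices].mean(axis=1)
        E_av = avatar_coords @ model.axes.T
        E_ce = centroid_coords @ model.axes.T
        for var in model.variables:
            lv = config.perturbation_level.get(var.name, 0.0)
            if lv > 0:
                E_av[:, var.cols] = (1 - lv) * E_av[:, var.cols] + lv * E_ce[:, var.cols]
        avatar_coords = E_av @ model.axes

    avatar_data_ordered = inverse_transform(model, avatar_coords)

    permutation = rng.permutation(n)
    shuffled = avatar_data_ordered.take(permutation)
    # shuffled row r holds the avatar of original row permutation[r]
    linkage = np.argsort(permutation, kind="stable")
    return AvatarDataset(
        data=shuffled,
        linkage=linkage,
        permutation=permutation,
        model=model,
        neighbor_model=nm,
        config=config,
        coordinates_pre_shuffle=avatar_coords,
    )


def avatarize(
    path_in: str | Path,
    config: AvatarConfig,
    path_out: str | Path,
    schema=None,
    report_path: str | Path | None = None,
) -> dict:
    """File-level orchestration: read, generate, write avatar CSV + report.

    The report (JSON) contains the privacy metrics and a run manifest
    (config, seed, software version); the linkage map is never written.
    """
    from .privacy import privacy_report  # local import to avoid a cycle

    original = read_dataset(path_in, schema=schema)
    result = generate_avatars(original, config)
    write_dataset(result.data, path_out)
    report = privacy_report(original, result)
    report["manifest"] = {
        "input": Path(path_in).name,
        "output": Path(path_out).name,
        "config": config.to_dict(),
        "software_version": __version__,
        "n": original.n,
        "p": original.p,
    }
    if report_path is not None:
        Path(report_path).write_text(json.dumps(report, indent=2))
    return report
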