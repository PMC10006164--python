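"""Factor analysis of mixed data (FAMD) with an exact full-rank inverse.

Continuous variables (and dates, via their days-since-epoch embedding)
are standardized to mean 0 / sd 1; each categorical level is one-hot
encoded, the indicator divided by ``sqrt(proportion)`` and centered.
With this encoding the squared Euclidean distance between two records
combines the z-score distance on continuous variables with the
chi-square-style distance on categoricals, so a single PCA of the
encoded matrix treats both on one scale.  Optional per-variable weights
multiply the encoded columns and therefore scale each variable's
influence on every downstream distance.

The model always retains the *full* rank of the encoded matrix: the
axes span the whole row space, so ``inverse_transform(transform(x))``
reconstructs the encoded values exactly and categorical levels decode
without loss.  Dimension reduction for neighbor search is the caller's
concern (take the first ``nd`` coordinate columns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import TabularDataset, VariableSpec, _EPOCH

__all__ = ["ProjectionModel", "ProjectionError", "fit_famd", "transform", "inverse_transform"]


class ProjectionError(ValueError):
    """The dataset cannot be projected (degenerate column, unseen label...)."""


@dataclass
class _EncodedVar:
    """Bookkeeping for one original variable's encoded columns."""

    name: str
    vtype: str
    cols: slice                      # position(s) in the encoded matrix
    weight: float
    center: np.ndarray               # per encoded column
    scale: np.ndarray                # per encoded column (sd or sqrt(prop))
    levels: tuple[str, ...] | None   # observed levels, categorical only
    proportions: np.ndarray | None   # training proportions per observed level


@dataclass
class ProjectionModel:
    variables: list[_EncodedVar]
    axes: np.ndarray                  # (encoded_dim, ncomp), orthonormal columns
    singular_values: np.ndarray       # length ncomp, non-increasing
    explained_variance_ratio: np.ndarray
    n_fit: int
    schema: list[VariableSpec]

    @property
    def ncomp(self) -> int:
        return self.axes.shape[1]

    @property
    def encoded_dim(self) -> int:
        return self.axes.shape[0]

    def component_sd(self) -> np.ndarray:
        """Standard deviation of each component score over the training data."""
        return self.singular_values / np.sqrt(self.n_fit)

    def nd_for_variance(self, target: float = 0.90) -> int:
        """Smallest component count reaching ``target`` cumulative variance."""
        cum = np.cumsum(self.explained_variance_ratio)
        return int(np.searchsorted(cum, target - 1e-12) + 1) if cum.size else 0

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_fit": self.n_fit,
            "axes": self.axes.tolist(),
            "singular_values": self.singular_values.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "schema": [
                {
                    "name": v.name,
                    "vtype": v.vtype,
                    "categories": list(v.categories) if v.categories else None,
                    "weight": v.weight,
                }
                for v in self.schema
            ],
            "variables": [
                {
                    "name": v.name,
                    "vtype": v.vtype,
                    "cols": [v.cols.start, v.cols.stop],
                    "weight": v.weight,
                    "center": v.center.tolist(),
                    "scale": v.scale.tolist(),
                    "levels": list(v.levels) if v.levels else None,
                    "proportions": v.proportions.tolist()
                    if v.proportions is not None
                    else None,
                }
            for v in self.variables],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProjectionModel":
        doc = json.loads(Path(path).read_text())
        schema = [
            VariableSpec(
                s["name"],
                s["vtype"],
                tuple(s["categories"]) if s["categories"] and s["vtype"] == "categorical" else None,
                s["weight"],
            )
            for s in doc["schema"]
        ]
        variables = [
            _EncodedVar(
                name=v["name"],
                vtype=v["vtype"],
                cols=slice(v["cols"][0], v["cols"][1]),
                weight=v["weight"],
                center=np.asarray(v["center"], dtype=float),
                scale=np.asarray(v["scale"], dtype=float),
                levels=tuple(v["levels"]) if v["levels"] else None,
                proportions=np.asarray(v["proportions"], dtype=float)
                if v["proportions"] is not None
                else None,
            )
            for v in doc["variables"]
        ]
        return cls(
            variables=variables,
            axes=np.asarray(doc["axes"], dtype=float),
            singular_values=np.asarray(doc["singular_values"], dtype=float),
            explained_variance_ratio=np.asarray(
                doc["explained_variance_ratio"], dtype=float
            ),
            n_fit=doc["n_fit"],
            schema=schema,
        )


def _encode_with(model: ProjectionModel, data: TabularDataset) -> np.ndarray:
    """Encode ``data`` using the model's centers/scales (no refit)."""
    n = data.n
    out = np.empty((n, model.encoded_dim), dtype=np.float64)
    for var in model.variables:
        if var.levels is None:
            x = data.numeric_view(var.name)
            out[:, var.cols] = (
                ((x - var.center[0]) / var.scale[0] * var.weight)[:, None]
            )
        else:
            col = data.frame[var.name]
            unseen = ~col.isin(var.levels)
            if unseen.any():
                bad = col[unseen].iloc[0]
                raise ProjectionError(
                    f"label {bad!r} in column {var.name!r} was not observed "
                    "when the model was fitted"
                )
            codes = pd.Categorical(col, categories=var.levels).codes
            ind = np.zeros((n, len(var.levels)))
            ind[np.arange(n), codes] = 1.0
            out[:, var.cols] = (ind - var.center) / var.scale * var.weight
    return out


def fit_famd(
    data: TabularDataset, column_weights: dict[str, float] | None = None
) -> ProjectionModel:
    """Fit the mixed-data factor model on ``data``.

    The axes are the right singular vectors of the encoded matrix and every
    non-null component is kept (``ncomp`` = matrix rank), so the model is
    lossless.  ``column_weights`` override the per-variable weights carried
    by the schema.

    Raises
    ------
    ProjectionError
        For a zero-variance continuous column or a categorical column with
        a single observed level (neither can be standardized).
    """
    column_weights = column_weights or {}
    variables: list[_EncodedVar] = []
    pos = 0
    for spec in data.schema:
        w = float(column_weights.get(spec.name, spec.weight))
        if w <= 0:
            raise ProjectionError(f"weight for {spec.name!r} must be > 0")
        if spec.is_numeric:
            x = data.numeric_view(spec.name)
            sd = float(np.std(x))
            if sd == 0.0:
                raise ProjectionError(
                    f"continuous column {spec.name!r} has zero variance"
                )
            variables.append(
                _EncodedVar(
                    spec.name,
                    spec.vtype,
                    slice(pos, pos + 1),
                    w,
                    np.array([np.mean(x)]),
                    np.array([sd]),
                    None,
                    None,
                )
            )
            pos += 1
        else:
            counts = data.frame[spec.name].value_counts()
            levels = tuple(l for l in spec.categories if l in counts.index)
            if len(levels) < 2:
                raise ProjectionError(
                    f"categorical column {spec.name!r} has a single observed level"
                )
            props = np.array([counts[l] / data.n for l in levels])
            variables.append(
                _EncodedVar(
                    spec.name,
                    spec.vtype,
                    slice(pos, pos + len(levels)),
                    w,
                    props,                # centering at the proportion
                    np.sqrt(props),       # 1/sqrt(prop) scaling
                    levels,
                    props,
                )
            )
            pos += len(levels)

    model = ProjectionModel(
        variables=variables,
        axes=np.eye(pos),  # placeholder so _encode_with sees encoded_dim
        singular_values=np.empty(0),
        explained_variance_ratio=np.empty(0),
        n_fit=data.n,
        schema=list(data.schema),
    )
    Z = _encode_with(model, data)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    tol = max(Z.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    model.axes = vt[:rank].T
    model.singular_values = s[:rank]
    total = float(np.sum(s**2))
    model.explained_variance_ratio = (
        s[:rank] ** 2 / total if total > 0 else np.zeros(rank)
    )
    return model


def transform(model: ProjectionModel, data: TabularDataset) -> np.ndarray:
    """Project ``data`` into the model's component space (rows x ncomp)."""
    return _encode_with(model, data) @ model.axes


def inverse_transform(model: ProjectionModel, coords: np.ndarray) -> TabularDataset:
    """Map component scores back to schema values.

    Continuous values are un-scaled and un-centered reals; dates are rounded
    to whole days; each categorical column takes the level whose
    reconstructed indicator is largest, ties broken toward the level with
    the higher training proportion, then lexicographically.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != model.ncomp:
        raise ProjectionError(
            f"coordinates must be (n, {model.ncomp}), got {coords.shape}"
        )
    if not np.all(np.isfinite(coords)):
        raise ProjectionError("non-finite coordinates")
    E = coords @ model.axes.T
    out: dict[str, object] = {}
    for var in model.variables:
        block = E[:, var.cols] / var.weight
        if var.levels is None:
            x = block[:, 0] * var.scale[0] + var.center[0]
            if var.vtype == "date":
                days = np.rint(x).astype(np.int64)
                out[var.name] = _EPOCH + days.astype("timedelta64[D]")
            else:
                out[var.name] = x
        else:
            ind = block * var.scale + var.center  # reconstructed indicators
            # preference rank for exact ties: higher training proportion,
            # then lexicographically earlier level
            pref = np.empty(len(var.levels))
            by_pref = sorted(
                range(len(var.levels)),
                key=lambda i: (-var.proportions[i], var.levels[i]),
            )
            for rank_i, li in enumerate(by_pref):
                pref[li] = -rank_i  # higher is preferred
            best = np.argmax(ind, axis=1)
            top = ind.max(axis=1, keepdims=True)
            for i in np.nonzero((ind == top).sum(axis=1) > 1)[0]:
                tied = np.nonzero(ind[i] == top[i, 0])[0]
                best[i] = max(tied, key=lambda j: pref[j])
            out[var.name] = np.array(var.levels, dtype=object)[best]
    frame = pd.DataFrame(out, columns=[v.name for v in model.variables])
    return TabularDataset(list(model.schema), frame)
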