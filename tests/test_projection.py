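import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from avatarize import (
    ProjectionError,
    ProjectionModel,
    TabularDataset,
    VariableSpec,
    fit_famd,
    inverse_transform,
    transform,
)


def _continuous_table(X: np.ndarray) -> TabularDataset:
    frame = pd.DataFrame({f"x{j}": X[:, j] for j in range(X.shape[1])})
    return TabularDataset(
        [VariableSpec(f"x{j}", "continuous") for j in range(X.shape[1])], frame
    )


def test_all_continuous_reduces_to_standardized_pca():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 3)) @ np.diag([3.0, 1.0, 0.3])
    d = _continuous_table(X)
    model = fit_famd(d)
    scores = transform(model, d)

    # oracle: direct SVD of the z-scored matrix
    Z = (X - X.mean(0)) / X.std(0)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    oracle = Z @ vt.T
    assert scores.shape == oracle[:, : model.ncomp].shape
    for c in range(model.ncomp):  # per-component sign is arbitrary
        sign = np.sign(scores[0, c] * oracle[0, c]) or 1.0
        npt.assert_allclose(scores[:, c], sign * oracle[:, c], atol=1e-8)
    npt.assert_allclose(
        model.explained_variance_ratio, s**2 / np.sum(s**2), atol=1e-10
    )


def test_all_categorical_matches_mca_oracle():
    """On a pure-categorical toy table the component scores must be
    proportional to classical MCA row coordinates, component by component."""
    frame = pd.DataFrame(
        {
            "c1": ["a", "a", "b", "b", "a", "b"],
            "c2": ["u", "v", "u", "v", "v", "v"],
        }
    )
    d = TabularDataset(
        [
            VariableSpec("c1", "categorical", ("a", "b")),
            VariableSpec("c2", "categorical", ("u", "v")),
        ],
        frame,
    )
    model = fit_famd(d)
    scores = transform(model, d)

    # oracle: hand-rolled correspondence analysis of the indicator matrix
    levels = [("c1", "a"), ("c1", "b"), ("c2", "u"), ("c2", "v")]
    Z = np.array(
        [[1.0 if frame[c][i] == l else 0.0 for (c, l) in levels] for i in range(6)]
    )
    P = Z / Z.sum()
    r = P.sum(1)
    c = P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, s, vt = np.linalg.svd(S, full_matrices=False)
    keep = s > 1e-10
    mca_rows = (u[:, keep] * s[keep]) / np.sqrt(r)[:, None]

    assert scores.shape[1] == int(keep.sum())
    for comp in range(scores.shape[1]):
        a, b = scores[:, comp], mca_rows[:, comp]
        corr = abs(np.corrcoef(a, b)[0, 1])
        assert corr > 1 - 1e-8  # equal up to per-component scaling and sign


def test_rank_complete_two_column_case():
    frame = pd.DataFrame({"x": [0.0, 1.0, 2.0, 4.0], "g": ["a", "a", "b", "b"]})
    d = TabularDataset(
        [VariableSpec("x", "continuous"), VariableSpec("g", "categorical", ("a", "b"))],
        frame,
    )
    model = fit_famd(d)
    npt.assert_allclose(model.explained_variance_ratio.sum(), 1.0, atol=1e-10)
    gram = model.axes.T @ model.axes
    npt.assert_allclose(gram, np.eye(model.ncomp), atol=1e-8)
    assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)


def test_transform_consistency_and_duplicates(mixed_small):
    model = fit_famd(mixed_small)
    scores = transform(model, mixed_small)
    npt.assert_array_equal(scores, transform(model, mixed_small))
    doubled = mixed_small.take(list(range(mixed_small.n)) + [0, 1])
    sc2 = transform(model, doubled)
    npt.assert_allclose(sc2[-2], sc2[0], atol=1e-12)
    npt.assert_allclose(sc2[-1], sc2[1], atol=1e-12)


def test_mean_record_maps_to_origin():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 3))
    d = _continuous_table(X)
    model = fit_famd(d)
    mean_row = _continuous_table(np.vstack([X.mean(0), X.mean(0)]))
    npt.assert_allclose(transform(model, mean_row), 0.0, atol=1e-10)


def test_full_rank_round_trip(mixed_small):
    model = fit_famd(mixed_small)
    back = inverse_transform(model, transform(model, mixed_small))
    for j in range(4):
        npt.assert_allclose(
            back.numeric_view(f"x{j}"), mixed_small.numeric_view(f"x{j}"), rtol=1e-8
        )
    assert (back.frame["group"] == mixed_small.frame["group"]).all()


def test_zero_coordinates_decode_to_center(mixed_small):
    model = fit_famd(mixed_small)
    rec = inverse_transform(model, np.zeros((2, model.ncomp)))
    for j in range(4):
        npt.assert_allclose(
            rec.numeric_view(f"x{j}")[0],
            mixed_small.numeric_view(f"x{j}").mean(),
            rtol=1e-8,
        )
    # zero indicator block decodes to the majority level
    modal = mixed_small.frame["group"].value_counts().idxmax()
    assert rec.frame["group"][0] == modal


def test_convex_combination_is_linear_in_continuous_values():
    frame = pd.DataFrame({"a": [2.0, 10.0, 4.0], "b": [-1.0, 3.0, 0.0]})
    d = _continuous_table(frame.to_numpy())
    model = fit_famd(d)
    co = transform(model, d)
    lam = 0.25
    mix = lam * co[0] + (1 - lam) * co[1]
    rec = inverse_transform(model, np.vstack([mix, mix]))
    npt.assert_allclose(rec.numeric_view("x0")[0], lam * 2.0 + (1 - lam) * 10.0, rtol=1e-8)
    npt.assert_allclose(rec.numeric_view("x1")[0], lam * -1.0 + (1 - lam) * 3.0, rtol=1e-8)


def test_coordinate_distances_equal_encoded_distances(mixed_small):
    from avatarize.projection import _encode_with

    model = fit_famd(mixed_small)
    co = transform(model, mixed_small)
    Z = _encode_with(model, mixed_small)
    npt.assert_allclose(pdist(co), pdist(Z), rtol=1e-8, atol=1e-8)


def test_column_weights_scale_influence(mixed_small):
    heavy = fit_famd(mixed_small, column_weights={"x0": 10.0})
    co = transform(heavy, mixed_small)
    back = inverse_transform(heavy, co)
    npt.assert_allclose(back.numeric_view("x0"), mixed_small.numeric_view("x0"), rtol=1e-8)
    # the weighted variable dominates total encoded variance
    from avatarize.projection import _encode_with

    Z = _encode_with(heavy, mixed_small)
    var = Z.var(0)
    assert var[0] > 0.5 * var.sum()


def test_degenerate_columns_rejected():
    with pytest.raises(ProjectionError, match="zero variance"):
        fit_famd(_continuous_table(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])))
    frame = pd.DataFrame({"g": ["a", "a", "a"]})
    d = TabularDataset([VariableSpec("g", "categorical", ("a", "b"))], frame)
    with pytest.raises(ProjectionError, match="single observed level"):
        fit_famd(d)


def test_unseen_category_label_rejected(mixed_small):
    model = fit_famd(mixed_small)
    frame = mixed_small.frame.copy()
    schema = [
        *mixed_small.schema[:-1],
        VariableSpec("group", "categorical", ("a", "b", "c", "z")),
    ]
    frame.loc[0, "group"] = "z"
    other = TabularDataset(schema, frame)
    with pytest.raises(ProjectionError, match="'z'"):
        transform(model, other)


def test_non_finite_coordinates_rejected(mixed_small):
    model = fit_famd(mixed_small)
    bad = np.zeros((2, model.ncomp))
    bad[0, 0] = np.nan
    with pytest.raises(ProjectionError, match="non-finite"):
        inverse_transform(model, bad)


def test_model_persistence_round_trip(tmp_path, mixed_small):
    model = fit_famd(mixed_small)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = ProjectionModel.from_json(path)
    npt.assert_array_equal(transform(loaded, mixed_small), transform(model, mixed_small))
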