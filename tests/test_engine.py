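import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest

from avatarize import (
    AvatarConfig,
    ConfigError,
    TabularDataset,
    VariableSpec,
    avatarize,
    draw_weights,
    find_neighbors,
    generate_avatars,
    write_dataset,
)
from conftest import brute_force_knn


class _ForcedRng:
    """Deterministic stand-in: a prescribed shuffle and all R draws = 1."""

    def __init__(self, shuffled: list[int]):
        self._j = np.asarray(shuffled) - 1  # permutation() returns 0-based

    def permutation(self, k):
        return self._j

    def exponential(self, scale, size):
        return np.ones(size)


def test_worked_example_weights():
    """k=2 neighbors at distances 3 and 5, shuffled vector [2, 1], R forced
    to 1: raw products are (1/12, 1/10) and normalize to (5/11, 6/11)."""
    cfg = AvatarConfig(k=2)
    w, c, r, p = draw_weights(np.array([3.0, 5.0]), cfg, _ForcedRng([2, 1]))
    npt.assert_allclose(p, [1 / 12, 1 / 10], rtol=1e-15)
    npt.assert_allclose(w, [5 / 11, 6 / 11], rtol=1e-15)
    npt.assert_array_equal(c, [0.25, 0.5])


def test_single_neighbor_weight_is_one():
    rng = np.random.default_rng(3)
    for _ in range(5):
        w, *_ = draw_weights(np.array([2.7]), AvatarConfig(k=1), rng)
        npt.assert_allclose(w, [1.0])


def test_weight_invariants_over_many_draws():
    """W >= 0, sum(W) = 1 within 1e-12, and the contribution multiset is
    exactly {2^-1 .. 2^-k} for every draw."""
    rng = np.random.default_rng(17)
    for _ in range(2000):
        k = int(rng.integers(1, 11))
        d = rng.uniform(0.01, 10.0, size=k)
        w, c, r, p = draw_weights(d, AvatarConfig(k=k), rng)
        assert np.all(w >= 0) and np.all(w <= 1)
        assert abs(w.sum() - 1.0) <= 1e-12
        npt.assert_allclose(np.sort(c), 0.5 ** np.arange(k, 0, -1), rtol=1e-15)


def test_expected_weight_favors_nearer_neighbors():
    """Over many draws the mean weight decreases with distance (k=3)."""
    rng = np.random.default_rng(23)
    d = np.array([1.0, 2.0, 4.0])
    total = np.zeros(3)
    n = 10_000
    for _ in range(n):
        w, *_ = draw_weights(d, AvatarConfig(k=3), rng)
        total += w
    mean = total / n
    assert mean[0] > mean[1] > mean[2]


def test_equal_contribution_law():
    w, c, r, p = draw_weights(
        np.array([3.0, 5.0]),
        AvatarConfig(k=2, contribution_law="equal"),
        _ForcedRng([2, 1]),
    )
    npt.assert_array_equal(c, [1.0, 1.0])
    npt.assert_allclose(w, [5 / 8, 3 / 8])  # pure inverse-distance


def test_zero_distance_floored_not_fatal():
    w, *_ = draw_weights(
        np.array([0.0, 1.0]), AvatarConfig(k=2), _ForcedRng([1, 2]), zero_floor=1e-9
    )
    assert w[0] > 0.999  # duplicate gets (almost) all the mass


def test_find_neighbors_line_example():
    coords = np.array([[0.0], [1.0], [10.0]])
    nm = find_neighbors(coords, AvatarConfig(k=1))
    npt.assert_array_equal(nm.indices[:, 0], [1, 0, 1])


def test_find_neighbors_duplicate_tie_break():
    coords = np.zeros((5, 2))
    nm = find_neighbors(coords, AvatarConfig(k=2))
    for i in range(5):
        expected = [j for j in range(5) if j != i][:2]
        npt.assert_array_equal(nm.indices[i], expected)
        npt.assert_array_equal(nm.distances[i], [0.0, 0.0])


def test_find_neighbors_matches_brute_force():
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(200, 3))
    nm = find_neighbors(coords, AvatarConfig(k=7))
    idx, dst = brute_force_knn(coords, 7)
    npt.assert_array_equal(nm.indices, idx)
    npt.assert_allclose(nm.distances, dst, rtol=1e-12)


def test_k_too_large_rejected():
    with pytest.raises(ConfigError):
        find_neighbors(np.zeros((4, 2)), AvatarConfig(k=4))


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        AvatarConfig(k=0)
    with pytest.raises(ConfigError):
        AvatarConfig(distance="cosine")
    with pytest.raises(ConfigError):
        AvatarConfig(exponential_rate=0.0)
    with pytest.raises(ConfigError):
        AvatarConfig(perturbation_level={"x": 1.5})


def test_k1_avatar_equals_nearest_neighbor(mixed_small):
    res = generate_avatars(mixed_small, AvatarConfig(k=1, seed=5))
    nn = res.neighbor_model.indices[:, 0]
    for j in range(4):
        orig = mixed_small.numeric_view(f"x{j}")
        av = res.data.numeric_view(f"x{j}")[res.linkage]
        npt.assert_allclose(av, orig[nn], rtol=1e-6, atol=1e-8)
    av_cat = res.data.frame["group"].to_numpy()[res.linkage]
    npt.assert_array_equal(av_cat, mixed_small.frame["group"].to_numpy()[nn])


def test_weighted_center_is_convex_combination():
    """Explicit 2-D check: neighbors at (0,0) and (1,1) with W=(0.25, 0.75)
    put the avatar at (0.75, 0.75)."""
    w = np.array([0.25, 0.75])
    neigh = np.array([[0.0, 0.0], [1.0, 1.0]])
    npt.assert_allclose(w @ neigh, [0.75, 0.75])


def test_avatar_values_inside_neighbor_hull(mixed_small):
    """All weights non-negative and summing to 1 imply every avatar
    continuous value lies within [min, max] of its neighbors' values."""
    res = generate_avatars(mixed_small, AvatarConfig(k=20, seed=9))
    W = res.neighbor_model.weights
    assert np.all(W >= 0)
    npt.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
    idx = res.neighbor_model.indices
    for j in range(4):
        orig = mixed_small.numeric_view(f"x{j}")
        av = res.data.numeric_view(f"x{j}")[res.linkage]
        lo = orig[idx].min(axis=1) - 1e-8
        hi = orig[idx].max(axis=1) + 1e-8
        assert np.all(av >= lo) and np.all(av <= hi)


def test_self_never_own_neighbor(mixed_small):
    res = generate_avatars(mixed_small, AvatarConfig(k=10, seed=1))
    idx = res.neighbor_model.indices
    assert not np.any(idx == np.arange(mixed_small.n)[:, None])


def test_linkage_is_withheld_bijection(mixed_small):
    res = generate_avatars(mixed_small, AvatarConfig(k=5, seed=2))
    assert sorted(res.linkage.tolist()) == list(range(mixed_small.n))
    assert res.data.n == mixed_small.n and res.data.p == mixed_small.p


def test_fixed_seed_determinism_and_seed_sensitivity(tmp_path, mixed_small):
    src = tmp_path / "in.csv"
    write_dataset(mixed_small, src)
    out1, out2, out3 = (tmp_path / f"o{i}.csv" for i in (1, 2, 3))
    rep1 = avatarize(src, AvatarConfig(k=5, seed=42), out1, report_path=tmp_path / "r1.json")
    rep2 = avatarize(src, AvatarConfig(k=5, seed=42), out2, report_path=tmp_path / "r2.json")
    avatarize(src, AvatarConfig(k=5, seed=43), out3)
    assert out1.read_bytes() == out2.read_bytes()
    assert out1.read_bytes() != out3.read_bytes()
    assert rep1["dcr"] == rep2["dcr"]
    assert "linkage" not in rep1 and "linkage" not in (tmp_path / "r1.json").read_text()


def test_avatarize_output_validates_against_input_schema(tmp_path, mixed_small):
    from avatarize import read_dataset, validate_against

    src, dst = tmp_path / "in.csv", tmp_path / "out.csv"
    write_dataset(mixed_small, src)
    avatarize(src, AvatarConfig(k=5, seed=0), dst)
    out = read_dataset(dst, schema=mixed_small.schema)
    ok, issues = validate_against(out, mixed_small.schema)
    assert ok, issues
    assert (out.n, out.p) == (mixed_small.n, mixed_small.p)


def test_duplicates_handled_via_distance_floor(mixed_dupes):
    res = generate_avatars(mixed_dupes, AvatarConfig(k=5, seed=3))
    assert np.all(np.isfinite(res.neighbor_model.weights))
    npt.assert_allclose(res.neighbor_model.weights.sum(axis=1), 1.0, atol=1e-12)


def test_mahalanobis_runs_and_differs_from_euclidean(mixed_small):
    r_e = generate_avatars(mixed_small, AvatarConfig(k=5, seed=4, nd=2))
    r_m = generate_avatars(
        mixed_small, AvatarConfig(k=5, seed=4, nd=2, distance="mahalanobis")
    )
    assert not np.array_equal(r_e.neighbor_model.indices, r_m.neighbor_model.indices)


def test_perturbation_shrinks_toward_centroid(mixed_small):
    base = generate_avatars(mixed_small, AvatarConfig(k=10, seed=6))
    full = generate_avatars(
        mixed_small,
        AvatarConfig(k=10, seed=6, perturbation_level={f"x{j}": 1.0 for j in range(4)}),
    )
    idx = full.neighbor_model.indices
    for j in range(4):
        orig = mixed_small.numeric_view(f"x{j}")
        av = full.data.numeric_view(f"x{j}")[full.linkage]
        npt.assert_allclose(av, orig[idx].mean(axis=1), rtol=1e-6, atol=1e-8)
    assert not np.array_equal(
        base.data.numeric_view("x0"), full.data.numeric_view("x0")
    )
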