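import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialsig.core_io import ReferencePolyline
from spatialsig.spatialtime import (
    binned_profile,
    concatenate_samples,
    point_segment_distance,
    polyline_distances,
    profile_contrast,
    spatial_time,
)

from conftest import make_dataset


def brute_polyline_distance(points, polyline, samples_per_segment=1000):
    """Oracle: dense sampling of every segment."""
    verts = polyline.vertices
    sampled = []
    for a, b in zip(verts[:-1], verts[1:]):
        t = np.linspace(0, 1, samples_per_segment)[:, None]
        sampled.append(a + t * (b - a))
    sampled = np.vstack(sampled)
    d = np.linalg.norm(points[:, None, :] - sampled[None, :, :], axis=2)
    return d.min(axis=1)


def test_point_on_segment():
    assert point_segment_distance((0.5, 0), (0, 0), (1, 0)) == 0.0


def test_perpendicular_foot():
    assert point_segment_distance((0, 1), (0, 0), (1, 0)) == pytest.approx(1.0)


def test_endpoint_case():
    assert point_segment_distance((2, 1), (0, 0), (1, 0)) == pytest.approx(math.sqrt(2))


def test_degenerate_segment_is_point_distance():
    assert point_segment_distance((3, 4), (0, 0), (0, 0)) == pytest.approx(5.0)


def _line_dataset(raw_y, regions=None, sample="s1"):
    coords = np.column_stack([np.zeros(len(raw_y)), raw_y])
    counts = np.ones((2, len(raw_y)), dtype=int)
    return make_dataset(counts, regions=regions, coords=coords, sample=sample)


def _hline(sample="s1"):
    return ReferencePolyline(sample, np.array([[-10.0, 0.0], [10.0, 0.0]]))


def test_affine_scaling_three_spots():
    ds = _line_dataset([2.0, 4.0, 6.0])
    res = spatial_time(ds, _hline(), ["r"])
    assert np.allclose(res.table["raw_dist"], [2, 4, 6])
    assert np.allclose(res.table["st"], [0, 0.5, 1])


def test_perpendicular_ray_positions():
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = spatial_time(_line_dataset(y), _hline(), ["r"])
    assert np.allclose(res.table["st"], (y - 1) / 4)


def test_raw_distance_matches_dense_sampling():
    rng = np.random.default_rng(0)
    pts = rng.uniform(-5, 5, size=(40, 2))
    poly = ReferencePolyline("s", rng.uniform(-5, 5, size=(4, 2)))
    fast = polyline_distances(pts, poly)
    slow = brute_polyline_distance(pts, poly)
    assert np.allclose(fast, slow, rtol=1e-5, atol=1e-5)
    assert np.all(fast <= slow + 1e-12)  # dense sampling can only overestimate


def test_too_few_spots_is_error():
    ds = _line_dataset([1.0])
    with pytest.raises(ValueError, match=">= 2"):
        spatial_time(ds, _hline(), ["r"])


def test_degenerate_distances_flagged():
    ds = _line_dataset([3.0, 3.0, 3.0])
    res = spatial_time(ds, _hline(), ["r"])
    assert res.degenerate and np.all(res.table["st"] == 0)


def test_region_filter_and_sample_match():
    regions = ["in", "in", "out", "in"]
    ds = _line_dataset([1.0, 2.0, 3.0, 4.0], regions=regions)
    res = spatial_time(ds, _hline(), ["in"])
    assert len(res.table) == 3 and "out" not in set(res.table["region"])


def test_concatenate_preserves_per_sample_scaling():
    a = spatial_time(_line_dataset([1.0, 3.0], sample="sa"), _hline("sa"), ["r"])
    b = spatial_time(_line_dataset([2.0, 10.0], sample="sb"), _hline("sb"), ["r"])
    pooled = concatenate_samples(a, b)
    assert len(pooled.table) == 4
    for sid in ("sa", "sb"):
        sub = pooled.table[pooled.table["sample_id"] == sid]
        assert sub["st"].min() == 0 and sub["st"].max() == 1


def test_concatenate_single_is_identity():
    a = spatial_time(_line_dataset([1.0, 3.0]), _hline(), ["r"])
    pooled = concatenate_samples(a)
    assert pooled.table.equals(a.table)


def test_concatenate_duplicate_error():
    a = spatial_time(_line_dataset([1.0, 3.0]), _hline(), ["r"])
    with pytest.raises(ValueError, match="duplicate"):
        concatenate_samples(a, a)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_rigid_motion_and_scale_invariance(seed):
    rng = np.random.default_rng(seed)
    y = rng.uniform(0.5, 9, size=6)
    coords = np.column_stack([rng.uniform(-3, 3, 6), y])
    ds = make_dataset(np.ones((2, 6), dtype=int), coords=coords)
    poly = _hline()
    base = spatial_time(ds, poly, ["r"]).table["st"].to_numpy()

    theta = rng.uniform(0, 2 * np.pi)
    scale = rng.uniform(0.1, 10)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shift = rng.uniform(-50, 50, 2)
    new_coords = scale * coords @ rot.T + shift
    new_verts = scale * poly.vertices @ rot.T + shift
    ds2 = make_dataset(np.ones((2, 6), dtype=int), coords=new_coords)
    moved = spatial_time(
        ds2, ReferencePolyline("s1", new_verts), ["r"]
    ).table["st"].to_numpy()
    assert np.allclose(base, moved, atol=1e-9)


def test_binned_profile_constant_values():
    res = spatial_time(_line_dataset(np.linspace(1, 5, 20)), _hline(), ["r"])
    prof = binned_profile(res, np.full(20, 3.5), n_bins=4)
    assert np.allclose(prof.loc[prof["n"] > 0, "mean"], 3.5)


def test_binned_profile_identity_values():
    y = np.linspace(1, 2, 4000)
    res = spatial_time(_line_dataset(y), _hline(), ["r"])
    st_vals = res.table["st"].to_numpy()
    prof = binned_profile(res, st_vals, n_bins=4)
    assert np.allclose(prof["mean"], [0.125, 0.375, 0.625, 0.875], atol=0.01)
    assert prof["n"].sum() == 4000


def test_binned_profile_empty_bin():
    res = spatial_time(_line_dataset([1.0, 1.01, 5.0]), _hline(), ["r"])
    prof = binned_profile(res, np.array([1.0, 2.0, 3.0]), n_bins=4)
    empty = prof[prof["n"] == 0]
    assert len(empty) > 0 and empty["mean"].isna().all()


def test_profile_contrast_shapes():
    a = spatial_time(_line_dataset(np.linspace(1, 5, 30), sample="sa"), _hline("sa"), ["r"])
    b = spatial_time(_line_dataset(np.linspace(1, 5, 30), sample="sb"), _hline("sb"), ["r"])
    va = np.ones(30)
    vb = np.zeros(30)
    cmp_tbl = profile_contrast(a, va, b, vb, n_bins=5)
    assert len(cmp_tbl) == 5
    filled = cmp_tbl.dropna(subset=["diff"])
    assert np.allclose(filled["diff"], 1.0)
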