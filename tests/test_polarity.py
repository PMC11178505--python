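"""Polarity calling: cluster extraction, hull rule, angles, invariances."""

import numpy as np
import pytest

from polarcell.errors import UndefinedAngle, UndefinedDirection
from polarcell.kmeans1d import kmeans_1d
from polarcell.polarity import (
    PolarityCall,
    cluster_direction,
    extract_clusters,
    hull_polarity_test,
    polarization_angle,
    score_cell,
)
from polarcell.preprocess import (
    CellMask,
    compute_geometry,
    exclusion_area,
)
from polarcell.synth import ChannelSpec, SyntheticCellSpec, make_cell

from conftest import disk_mask, make_cluster, points_in_hull_oracle


def geom_disk(radius=40, center=(64, 64)):
    return compute_geometry(CellMask(disk_mask(center=center,
                                               radius=radius)))


def bins_for(img, mask, k=5):
    return kmeans_1d(img[mask], k=k)


def put_blob(img, y, x, n, value=100.0):
    """Paint an 8-connected blob of exactly n pixels near (y, x)."""
    coords = [(y, x), (y, x + 1), (y + 1, x), (y + 1, x + 1),
              (y, x + 2), (y + 1, x + 2), (y + 2, x), (y + 2, x + 1)]
    for yy, xx in coords[:n]:
        img[yy, xx] = value
    return img


# ---------------------------------------------------------------------------
# cluster extraction and the speckle rule


def test_speckle_smaller_than_five_pixels_is_removed(params):
    geom = geom_disk()
    img = np.ones(geom.mask.shape) * 10.0
    img[~geom.mask] = 0.0
    put_blob(img, 30, 60, 4)  # 4-px spot -> speckle, excluded
    bins = bins_for(img, geom.mask)
    clusters = extract_clusters(bins, img, geom, params)
    assert clusters == []


def test_five_pixel_cluster_survives(params):
    geom = geom_disk()
    img = np.ones(geom.mask.shape) * 10.0
    img[~geom.mask] = 0.0
    put_blob(img, 30, 60, 5)  # exactly 5 px -> retained
    bins = bins_for(img, geom.mask)
    clusters = extract_clusters(bins, img, geom, params)
    assert len(clusters) == 1
    assert clusters[0].size_px == 5


def test_two_opposite_caps_give_two_clusters(params):
    geom = geom_disk()
    img = np.ones(geom.mask.shape) * 10.0
    img[~geom.mask] = 0.0
    put_blob(img, 30, 62, 8)
    put_blob(img, 95, 62, 8)
    bins = bins_for(img, geom.mask)
    clusters = extract_clusters(bins, img, geom, params)
    assert len(clusters) == 2


def test_synthetic_cap_lands_in_top_bin_with_generator_size(params):
    spec = SyntheticCellSpec(
        channels=(ChannelSpec("a", polar_fraction=1.0,
                              cap_direction_deg=300.0),),
        noise_model="none",
        background_level=0.0,
    )
    stack, _ = make_cell(spec)
    img = stack.pixels[0, 0]
    from polarcell.synth import ellipse_mask

    mask = ellipse_mask(spec)
    geom = compute_geometry(CellMask(mask))
    bins = bins_for(img, mask)
    clusters = extract_clusters(bins, img, geom, params)
    assert len(clusters) == 1
    assert clusters[0].size_px == int((img > 0).sum())


# ---------------------------------------------------------------------------
# hull rule


def test_single_boundary_cap_is_polar(params):
    geom = geom_disk()
    disk = exclusion_area(geom, params)
    cap = np.argwhere(disk_mask(center=(64, 25), radius=6))[:, ::-1]
    assert hull_polarity_test([make_cluster(cap)], disk) is True


def test_antipodal_caps_hull_spans_the_center(params):
    geom = geom_disk()
    disk = exclusion_area(geom, params)
    cap1 = np.argwhere(disk_mask(center=(64, 25), radius=6))[:, ::-1]
    cap2 = np.argwhere(disk_mask(center=(64, 103), radius=6))[:, ::-1]
    assert hull_polarity_test(
        [make_cluster(cap1), make_cluster(cap2)], disk
    ) is False


def test_no_clusters_is_nonpolar(params):
    geom = geom_disk()
    disk = exclusion_area(geom, params)
    assert hull_polarity_test([], disk) is False


@pytest.mark.parametrize("seed", range(6))
def test_hull_rule_agrees_with_rasterized_oracle(params, seed):
    rng = np.random.default_rng(seed)
    geom = geom_disk()
    disk = exclusion_area(geom, params)
    dy, dx = np.nonzero(disk)
    disk_pts = np.column_stack([dx, dy])
    for _ in range(40):
        n_clusters = int(rng.integers(1, 4))
        clusters = []
        for _ in range(n_clusters):
            cy, cx = rng.integers(20, 108, size=2)
            n_px = int(rng.integers(5, 30))
            offs = rng.integers(-4, 5, size=(n_px, 2))
            pts = np.unique(
                np.clip(np.array([cx, cy]) + offs, 0, 127), axis=0
            )
            clusters.append(make_cluster(pts))
        result = hull_polarity_test(clusters, disk)
        all_pts = np.vstack([c.pixels for c in clusters])
        overlap = bool(points_in_hull_oracle(all_pts, disk_pts).any())
        assert result == (not overlap)


def test_growing_exclusion_radius_only_flips_polar_to_nonpolar(params):
    rng = np.random.default_rng(7)
    geom = geom_disk()
    for _ in range(20):
        cy, cx = rng.integers(20, 108, size=2)
        pts = np.unique(
            np.clip([cx, cy] + rng.integers(-6, 7, size=(12, 2)), 0, 127),
            axis=0,
        )
        clusters = [make_cluster(pts)]
        previous = True
        for radius in (5.0, 10.0, 20.0, 35.0):
            disk = exclusion_area(
                geom, params.replace(exclusion_radius_px=radius)
            )
            polar = hull_polarity_test(clusters, disk)
            assert not (polar and not previous)  # no nonpolar -> polar flip
            previous = polar


# ---------------------------------------------------------------------------
# directions and polarization angles


def test_direction_along_major_axis_gives_zero_angle(params):
    mask = np.zeros((128, 128), dtype=bool)
    yy, xx = np.mgrid[0:128, 0:128]
    mask[((xx - 64) / 40) ** 2 + ((yy - 64) / 20) ** 2 <= 1] = True
    geom = compute_geometry(CellMask(mask))
    img = np.ones(mask.shape)
    cap = np.argwhere(disk_mask(center=(98, 64), radius=4))[:, ::-1]
    _, to_axis = cluster_direction([make_cluster(cap)], geom, img)
    assert to_axis == pytest.approx(0.0, abs=1.0)


def test_direction_perpendicular_to_major_axis_gives_ninety(params):
    mask = np.zeros((128, 128), dtype=bool)
    yy, xx = np.mgrid[0:128, 0:128]
    mask[((xx - 64) / 40) ** 2 + ((yy - 64) / 20) ** 2 <= 1] = True
    geom = compute_geometry(CellMask(mask))
    img = np.ones(mask.shape)
    cap = np.argwhere(disk_mask(center=(64, 80), radius=4))[:, ::-1]
    _, to_axis = cluster_direction([make_cluster(cap)], geom, img)
    assert to_axis == pytest.approx(90.0, abs=1.0)


def test_no_clusters_direction_undefined():
    geom = geom_disk()
    with pytest.raises(UndefinedDirection):
        cluster_direction([], geom, np.ones(geom.mask.shape))


def _call(channel, polar, direction):
    return PolarityCall(
        channel=channel, is_polar=polar, clusters=[],
        direction_deg=direction, angle_to_axis_deg=None,
    )


def test_polarization_angle_identity_and_fold():
    assert polarization_angle(
        _call("r", True, 50.0), _call("t", True, 50.0)
    ).angle_deg == 0.0
    assert polarization_angle(
        _call("r", True, 10.0), _call("t", True, 190.0)
    ).angle_deg == pytest.approx(180.0)
    # symmetric in argument order
    a = polarization_angle(_call("r", True, 20.0), _call("t", True, 300.0))
    b = polarization_angle(_call("t", True, 300.0), _call("r", True, 20.0))
    assert a.angle_deg == b.angle_deg == pytest.approx(80.0)


def test_polarization_angle_requires_both_polar():
    with pytest.raises(UndefinedAngle):
        polarization_angle(_call("r", True, 10.0), _call("t", False, None))


# ---------------------------------------------------------------------------
# whole-cell scoring


def _polar_two_channel_spec(seed, offset=45.0, noise="poisson"):
    return SyntheticCellSpec(
        channels=(
            ChannelSpec("tubulin", polar_fraction=0.7,
                        cap_direction_deg=120.0),
            ChannelSpec("marker", polar_fraction=0.7,
                        cap_direction_deg=(120.0 + offset) % 360.0),
        ),
        orientation_deg=30.0,
        noise_model=noise,
        seed=seed,
    )


def test_uniform_cell_scores_nonpolar_in_all_channels():
    spec = SyntheticCellSpec(
        channels=(ChannelSpec("tubulin"), ChannelSpec("marker")), seed=0
    )
    stack, _ = make_cell(spec)
    score = score_cell(stack)
    assert all(not c.is_polar for c in score.calls.values())
    assert score.angles == {}


def test_scoring_is_deterministic():
    stack, _ = make_cell(_polar_two_channel_spec(3))
    s1 = score_cell(stack)
    s2 = score_cell(stack)
    for name in s1.calls:
        assert s1.calls[name].is_polar == s2.calls[name].is_polar
        assert s1.calls[name].direction_deg == s2.calls[name].direction_deg


def test_polar_cell_recovers_programmed_offset_angle():
    stack, _ = make_cell(_polar_two_channel_spec(5))
    score = score_cell(stack)
    assert score.calls["tubulin"].is_polar
    assert score.calls["marker"].is_polar
    assert score.angles["marker"].angle_deg == pytest.approx(45.0, abs=15.0)


def test_intensity_scaling_leaves_calls_unchanged():
    stack, _ = make_cell(_polar_two_channel_spec(8))
    base = score_cell(stack)
    scaled_stack = type(stack)(stack.pixels * 3.7, stack.channel_names)
    scaled = score_cell(scaled_stack)
    for name in base.calls:
        assert base.calls[name].is_polar == scaled.calls[name].is_polar
        if base.calls[name].direction_deg is not None:
            assert scaled.calls[name].direction_deg == pytest.approx(
                base.calls[name].direction_deg, abs=1e-9
            )


def test_ninety_degree_rotation_rotates_directions_exactly():
    stack, _ = make_cell(_polar_two_channel_spec(11))
    base = score_cell(stack)
    rot = type(stack)(
        np.rot90(stack.pixels, axes=(2, 3)).copy(), stack.channel_names
    )
    rotated = score_cell(rot)
    for name in base.calls:
        assert base.calls[name].is_polar == rotated.calls[name].is_polar
        d0 = base.calls[name].direction_deg
        d1 = rotated.calls[name].direction_deg
        if d0 is not None:
            # rot90 maps (y, x) -> (N-1-x, y): directions shift by -90
            assert (d0 - d1) % 360.0 == pytest.approx(90.0, abs=1e-6)
    if "marker" in base.angles:
        assert rotated.angles["marker"].angle_deg == pytest.approx(
            base.angles["marker"].angle_deg, abs=1e-6
        )


def test_missing_reference_channel_is_an_error():
    stack, _ = make_cell(
        SyntheticCellSpec(channels=(ChannelSpec("a"),), seed=0)
    )
    with pytest.raises(ValueError, match="reference"):
        score_cell(stack, reference_channel="tubulin")
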