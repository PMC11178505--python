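"""Synthetic generator: conservation, limits, determinism, pair ratios."""

import numpy as np
import pytest

from polarcell.errors import EmptyCohort, InvalidSpec
from polarcell.synth import (
    ChannelSpec,
    SyntheticCellSpec,
    SyntheticPairSpec,
    classify_ratio,
    ellipse_mask,
    make_cell,
    make_cohort,
    make_pair,
    make_pair_cohort,
)


def cell_spec(**kwargs) -> SyntheticCellSpec:
    defaults = dict(
        channels=(ChannelSpec("a"),),
        noise_model="none",
        background_level=0.0,
    )
    defaults.update(kwargs)
    return SyntheticCellSpec(**defaults)


def pair_cells(chan_kwargs=None, canvas=(128, 192)):
    chans = (ChannelSpec("a", **(chan_kwargs or {})),)
    a = SyntheticCellSpec(
        channels=chans, center_px=(54.0, 64.0), semiaxes_px=(24, 20),
        canvas_shape=canvas, noise_model="none", background_level=0.0,
    )
    b = SyntheticCellSpec(
        channels=chans, center_px=(138.0, 64.0), semiaxes_px=(24, 20),
        canvas_shape=canvas, noise_model="none", background_level=0.0,
    )
    return a, b


# ---------------------------------------------------------------------------
# single cells


def test_uniform_limit_is_flat_and_nonpolar():
    spec = cell_spec(channels=(ChannelSpec("a", polar_fraction=0.0),))
    stack, truth = make_cell(spec)
    img = stack.pixels[0, 0]
    mask = ellipse_mask(spec)
    inside = img[mask]
    assert np.allclose(inside, inside[0])
    assert np.all(img[~mask] == 0.0)
    assert truth.is_polar["a"] is False


def test_fully_polarized_limit_concentrates_all_signal_in_the_cap():
    spec = cell_spec(
        semiaxes_px=(30.0, 30.0),  # circle: sector centroid is unbiased
        channels=(
            ChannelSpec(
                "a",
                polar_fraction=1.0,
                cap_direction_deg=30.0,
                cap_halfwidth_deg=30.0,
            ),
        )
    )
    stack, truth = make_cell(spec)
    img = stack.pixels[0, 0]
    assert truth.is_polar["a"] is True
    assert truth.true_direction_deg["a"] == 30.0
    ys, xs = np.nonzero(img)
    # all signal pixels sit in the programmed angular sector
    ang = np.degrees(np.arctan2(ys - 64.0, xs - 64.0)) % 360.0
    dang = np.abs((ang - 30.0 + 180.0) % 360.0 - 180.0)
    assert np.all(dang <= 30.0 + 1.0)  # +1 deg rasterization slack
    # and signal centroid points along the cap direction
    cy, cx = ys.mean(), xs.mean()
    assert np.degrees(np.arctan2(cy - 64, cx - 64)) % 360 == pytest.approx(
        30.0, abs=2.0
    )


def test_noiseless_within_mask_sum_equals_total_signal():
    spec = cell_spec(
        channels=(
            ChannelSpec("a", total_signal=10000.0, polar_fraction=0.6,
                        cap_direction_deg=200.0),
        )
    )
    stack, _ = make_cell(spec)
    assert stack.pixels[0, 0].sum() == pytest.approx(10000.0, rel=1e-9)


def test_conservation_with_speckles_included_in_budget():
    spec = cell_spec(
        channels=(
            ChannelSpec("a", total_signal=20000.0, n_speckles=3,
                        speckle_signal=1000.0, speckle_size_px=4),
        ),
        seed=1,
    )
    stack, _ = make_cell(spec)
    assert stack.pixels[0, 0].sum() == pytest.approx(20000.0, rel=1e-9)


def test_cap_pixels_touch_the_boundary_zone():
    from polarcell.preprocess import boundary_distance_map

    spec = cell_spec(
        channels=(
            ChannelSpec("a", polar_fraction=1.0, cap_direction_deg=90.0),
        )
    )
    stack, _ = make_cell(spec)
    mask = ellipse_mask(spec)
    bdist = boundary_distance_map(mask)
    ys, xs = np.nonzero(stack.pixels[0, 0])
    assert np.all(mask[ys, xs])
    assert np.all(bdist[ys, xs] <= spec.cap_depth_px)
    assert bdist[ys, xs].min() == 0.0  # reaches the boundary


def test_identical_seed_gives_bit_identical_images():
    spec = cell_spec(
        channels=(ChannelSpec("a", polar_fraction=0.7, n_speckles=2),),
        noise_model="poisson",
        background_level=8.0,
        seed=42,
    )
    s1, _ = make_cell(spec)
    s2, _ = make_cell(spec)
    assert np.array_equal(s1.pixels, s2.pixels)


def test_rotating_cap_direction_rotates_signal_centroid():
    base_dir = 0.0
    centroids = {}
    for delta in (0.0, 90.0, 180.0, 270.0):
        spec = cell_spec(
            semiaxes_px=(30.0, 30.0),  # circle: exact rasterization symmetry
            channels=(
                ChannelSpec("a", polar_fraction=1.0,
                            cap_direction_deg=base_dir + delta),
            ),
        )
        stack, _ = make_cell(spec)
        img = stack.pixels[0, 0]
        ys, xs = np.nonzero(img)
        w = img[ys, xs]
        ang = np.degrees(
            np.arctan2(np.average(ys, weights=w) - 64.0,
                       np.average(xs, weights=w) - 64.0)
        ) % 360.0
        centroids[delta] = ang
    for delta in (90.0, 180.0, 270.0):
        diff = (centroids[delta] - centroids[0.0]) % 360.0
        assert diff == pytest.approx(delta, abs=1e-6)


def test_ellipse_outside_canvas_is_rejected():
    with pytest.raises(InvalidSpec):
        cell_spec(center_px=(10.0, 64.0))  # default semiaxes overflow left


def test_multi_slice_stack_projects_back_to_signal():
    from polarcell.preprocess import z_project

    spec = cell_spec(
        channels=(ChannelSpec("a", total_signal=5000.0),), n_z=3
    )
    stack, _ = make_cell(spec)
    assert stack.pixels.shape[1] == 3
    proj = z_project(stack)
    assert proj.pixels[0].sum() == pytest.approx(5000.0, rel=1e-9)


# ---------------------------------------------------------------------------
# pairs


def test_equal_totals_give_unit_ratio_and_symmetric_truth():
    a, b = pair_cells()
    spec = SyntheticPairSpec(cell_a=a, cell_b=b, marker_ratio={"a": 1.0})
    stack, truth = make_pair(spec)
    assert truth.sister_ratio["a"] == 1.0
    assert truth.division_class["a"] == "symmetric"


def test_programmed_ratio_two_is_measured_exactly_noiseless():
    a, b = pair_cells()
    spec = SyntheticPairSpec(
        cell_a=a, cell_b=b, marker_ratio={"a": 2.0},
        high_daughter={"a": "B"},
    )
    stack, truth = make_pair(spec)
    img = stack.pixels[0, 0]
    from polarcell.synth import ellipse_mask

    sum_a = img[ellipse_mask(a)].sum()
    sum_b = img[ellipse_mask(b)].sum()
    assert max(sum_a, sum_b) / min(sum_a, sum_b) == pytest.approx(
        2.0, rel=1e-9
    )
    assert sum_b > sum_a
    assert truth.division_class["a"] == "asymmetric"


def test_overlapping_daughters_are_rejected():
    a, _ = pair_cells()
    b = SyntheticCellSpec(
        channels=a.channels, center_px=(70.0, 64.0), semiaxes_px=(24, 20),
        canvas_shape=(128, 192), noise_model="none", background_level=0.0,
    )
    with pytest.raises(InvalidSpec):
        make_pair(SyntheticPairSpec(cell_a=a, cell_b=b))


def test_ratio_below_one_is_rejected():
    a, b = pair_cells()
    with pytest.raises(InvalidSpec):
        SyntheticPairSpec(cell_a=a, cell_b=b, marker_ratio={"a": 0.8})


def test_truth_class_follows_threshold_rule():
    assert classify_ratio(1.0) == "symmetric"
    assert classify_ratio(1.19) == "symmetric"
    assert classify_ratio(1.2) == "indeterminate"
    assert classify_ratio(1.5) == "indeterminate"
    assert classify_ratio(1.51) == "asymmetric"


def test_noisy_measured_ratio_concentrates_near_programmed_value():
    # Monte-Carlo with the generator as its own oracle: Poisson counting
    # noise on ~5e4 photons keeps the measured sum ratio within 5% of the
    # programmed 1.6 in nearly all repeats
    a, b = pair_cells(chan_kwargs=dict(total_signal=5e4))
    a = SyntheticCellSpec(
        **{**a.__dict__, "noise_model": "poisson", "background_level": 0.0}
    )
    b = SyntheticCellSpec(
        **{**b.__dict__, "noise_model": "poisson", "background_level": 0.0}
    )
    mask_a, mask_b = ellipse_mask(a), ellipse_mask(b)
    n_ok = 0
    n_rep = 200
    for seed in range(n_rep):
        spec = SyntheticPairSpec(
            cell_a=a, cell_b=b, marker_ratio={"a": 1.6}, seed=seed
        )
        stack, _ = make_pair(spec)
        img = stack.pixels[0, 0]
        r = img[mask_a].sum() / img[mask_b].sum()
        r = max(r, 1 / r)
        n_ok += abs(r - 1.6) / 1.6 <= 0.05
    assert n_ok >= 0.95 * n_rep


# ---------------------------------------------------------------------------
# cohorts


def test_all_uniform_cohort_truth_is_nonpolar():
    cells, truth = make_cohort(10, polar_fraction_of_cohort=0.0, seed=0)
    assert len(cells) == 10
    assert not truth["is_polar"].any()


def test_cohort_reproducible_from_seed():
    cells1, t1 = make_cohort(5, seed=9)
    cells2, t2 = make_cohort(5, seed=9)
    for (s1, _), (s2, _) in zip(cells1, cells2):
        assert np.array_equal(s1.pixels, s2.pixels)
    assert t1.equals(t2)


def test_cohort_realized_polar_count_matches_mixture():
    from scipy.stats import binom

    n = 200
    cells, truth = make_cohort(n, polar_fraction_of_cohort=0.6, seed=2)
    per_cell = truth[truth["channel"] == "tubulin"]
    realized = int(per_cell["is_polar"].sum())
    lo, hi = binom.ppf([0.005, 0.995], n, 0.6)
    assert lo <= realized <= hi


def test_empty_cohort_is_rejected():
    with pytest.raises(EmptyCohort):
        make_cohort(0)
    with pytest.raises(EmptyCohort):
        make_pair_cohort(0)


def test_pair_cohort_truth_labels_consistent():
    pairs, truth = make_pair_cohort(6, ratio=2.0, seed=1)
    assert len(pairs) == 6
    assert set(truth["true_class"]) == {"asymmetric"}
    assert set(truth["channel"]) == {"numb", "cdc42"}
    # concordant by default: one high daughter per pair
    per_pair = truth.groupby("pair_id")["high_daughter"].nunique()
    assert (per_pair == 1).all()
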