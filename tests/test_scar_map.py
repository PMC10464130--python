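"""Intensity statistics, region growing, thresholds, and binary morphology."""

import numpy as np
import pytest

from radscar.errors import (
    EmptyMaskError,
    EmptyStructuringElementError,
    OutOfBoundsSeedError,
    ShapeMismatchError,
)
from radscar.phantom import PhantomSpec, generate_phantom
from radscar.scar_map import (
    RegionStats,
    StructuringElement,
    binarize_mean,
    closing,
    contrast_rule,
    dice,
    dilate,
    erode,
    opening,
    region_grow,
    region_grow_bfs,
    region_stats,
    robust_healthy_stats,
    scar_pipeline,
    scar_threshold,
)

CROSS = StructuringElement.cross3()
SQUARE = StructuringElement.square3()


# --- region statistics ------------------------------------------------------

def test_region_stats_constant_and_two_point():
    img = np.full((4, 4), 59.0)
    st = region_stats(img, np.ones((4, 4), dtype=bool))
    assert (st.mean, st.sd, st.n_pixels) == (59.0, 0.0, 16)

    img2 = np.array([[0.0, 10.0]])
    st2 = region_stats(img2, np.ones((1, 2), dtype=bool))
    assert (st2.mean, st2.sd) == (5.0, 5.0)  # population SD, divisor n


def test_region_stats_matches_loop_oracle(rng):
    img = rng.normal(50, 30, (32, 32))
    mask = rng.random((32, 32)) < 0.5
    st = region_stats(img, mask)
    vals = [img[r, c] for r in range(32) for c in range(32) if mask[r, c]]
    mean = sum(vals) / len(vals)
    sd = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
    assert st.mean == pytest.approx(mean, abs=1e-9)
    assert st.sd == pytest.approx(sd, abs=1e-9)
    assert st.n_pixels == len(vals)


def test_region_stats_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        region_stats(np.zeros((3, 3)), np.zeros((3, 3), dtype=bool))
    with pytest.raises(ShapeMismatchError):
        region_stats(np.zeros((3, 3)), np.ones((2, 2), dtype=bool))


def test_robust_stats_ignore_bright_minority(rng):
    vals = rng.normal(59, 21, 20_000)
    vals[:3000] = rng.normal(143, 7, 3000)  # 15% bright contamination
    img = vals.reshape(100, 200)
    st = robust_healthy_stats(img, np.ones_like(img, dtype=bool))
    assert st.mean == pytest.approx(59, abs=2.0)
    assert st.sd == pytest.approx(21, abs=2.0)


# --- region growing ---------------------------------------------------------

def test_region_grow_degenerate_tolerances():
    img = np.arange(16, dtype=float).reshape(4, 4)
    only_seed = region_grow(img, (2, 1), tolerance=0.0)
    assert only_seed.sum() == 1 and only_seed[2, 1]
    everything = region_grow(img, (0, 0), tolerance=np.inf)
    assert everything.all()


def test_region_grow_matches_bfs_oracle(rng):
    for _ in range(5):
        img = rng.integers(0, 40, (16, 16)).astype(float)
        seed = tuple(rng.integers(0, 16, 2))
        got = region_grow(img, seed, tolerance=10.0)
        oracle = region_grow_bfs(img, seed, tolerance=10.0)
        np.testing.assert_array_equal(got, oracle)
        assert got[seed]  # contains the seed


def test_region_grow_output_is_four_connected(rng):
    from scipy import ndimage

    img = rng.integers(0, 30, (20, 20)).astype(float)
    mask = region_grow(img, (10, 10), tolerance=8.0)
    n_components = ndimage.label(
        mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    )[1]
    assert n_components == 1


def test_region_grow_out_of_bounds_seed():
    with pytest.raises(OutOfBoundsSeedError):
        region_grow(np.zeros((4, 4)), (4, 0), 1.0)


# --- thresholds -------------------------------------------------------------

HEALTHY = RegionStats(mean=59.0, sd=21.0, n_pixels=100)


@pytest.mark.parametrize("k,value,expected", [
    (3.0, 123.0, True),     # cutoff 122
    (3.0, 123.5, True),
    (3.0, 122.0, False),    # strict inequality
    (3.0, 122.000001, True),
    (3.0, 121.999, False),
    (2.0, 101.5, True),     # cutoff 101
    (2.0, 101.0, False),
    (2.0, 100.9, False),
])
def test_threshold_cutoff_arithmetic(k, value, expected):
    img = np.full((1, 1), value)
    myo = np.ones((1, 1), dtype=bool)
    assert scar_threshold(img, myo, HEALTHY, k=k)[0, 0] == expected


def test_threshold_matches_loop_oracle_and_respects_mask(rng):
    img = rng.normal(80, 40, (24, 24))
    myo = rng.random((24, 24)) < 0.7
    got = scar_threshold(img, myo, HEALTHY, k=3.0)
    for r in range(24):
        for c in range(24):
            assert got[r, c] == (myo[r, c] and img[r, c] > 122.0)
    assert not (got & ~myo).any()


def test_threshold_all_at_mean_is_empty():
    img = np.full((5, 5), HEALTHY.mean)
    assert not scar_threshold(img, np.ones((5, 5), bool), HEALTHY, k=3).any()


def test_raising_k_never_adds_pixels(rng):
    img = rng.normal(80, 40, (24, 24))
    myo = np.ones((24, 24), dtype=bool)
    prev = scar_threshold(img, myo, HEALTHY, k=0.0)
    for k in (1.0, 2.0, 3.0, 4.0):
        cur = scar_threshold(img, myo, HEALTHY, k=k)
        assert not (cur & ~prev).any()
        prev = cur


def test_contrast_rule_equals_threshold_at_k2(rng):
    img = rng.normal(80, 40, (24, 24))
    myo = rng.random((24, 24)) < 0.8
    np.testing.assert_array_equal(
        contrast_rule(img, myo, HEALTHY), scar_threshold(img, myo, HEALTHY, k=2.0)
    )


def test_contrast_rule_sd_zero_degenerates_to_mean():
    st = RegionStats(mean=50.0, sd=0.0, n_pixels=10)
    img = np.array([[49.0, 50.0, 51.0]])
    myo = np.ones((1, 3), dtype=bool)
    np.testing.assert_array_equal(
        contrast_rule(img, myo, st), [[False, False, True]]
    )


def test_binarize_mean_examples_and_oracle(rng):
    const = np.full((3, 3), 7.0)
    assert not binarize_mean(const, np.ones((3, 3), bool)).any()

    img = np.array([[0.0, 0.0], [0.0, 100.0]])
    got = binarize_mean(img, np.ones((2, 2), bool))  # mean 25
    np.testing.assert_array_equal(got, [[False, False], [False, True]])

    img2 = rng.normal(0, 1, (16, 16))
    mask = rng.random((16, 16)) < 0.6
    got2 = binarize_mean(img2, mask)
    mean = img2[mask].mean()
    for r in range(16):
        for c in range(16):
            assert got2[r, c] == (mask[r, c] and img2[r, c] > mean)


# --- morphology -------------------------------------------------------------

def test_origin_only_element_is_identity(rng):
    se = StructuringElement(frozenset([(0, 0)]))
    mask = rng.random((10, 10)) < 0.5
    for op in (erode, dilate, opening, closing):
        np.testing.assert_array_equal(op(mask, se), mask)


def test_single_pixel_dilate_erode_textbook():
    mask = np.zeros((7, 7), dtype=bool)
    mask[3, 3] = True
    grown = dilate(mask, SQUARE)
    assert grown.sum() == 9 and grown[2:5, 2:5].all()
    np.testing.assert_array_equal(erode(grown, SQUARE), mask)


def test_empty_structuring_element_rejected():
    with pytest.raises(EmptyStructuringElementError):
        StructuringElement(frozenset())


@pytest.mark.parametrize("se", [CROSS, SQUARE], ids=["cross3", "square3"])
def test_morphology_algebra_on_random_masks(rng, se):
    for _ in range(20):
        mask = rng.random((20, 20)) < rng.uniform(0.2, 0.8)
        er, di = erode(mask, se), dilate(mask, se)
        op, cl = opening(mask, se), closing(mask, se)
        assert not (er & ~mask).any()          # erode subset id
        assert not (mask & ~di).any()          # id subset dilate
        assert not (op & ~mask).any()          # open subset id
        assert not (mask & ~cl).any()          # id subset close
        np.testing.assert_array_equal(opening(op, se), op)   # idempotent
        np.testing.assert_array_equal(closing(cl, se), cl)


@pytest.mark.parametrize("se", [CROSS, SQUARE], ids=["cross3", "square3"])
def test_erosion_dilation_duality_under_complement(rng, se):
    # the algebraic identity dilate(x) == ~erode(~x, reflected se) holds on
    # the infinite plane; pad with a false margin wider than the element so
    # the border rule (outside = false) cannot interfere, compare the core
    pad = 3
    for _ in range(20):
        core = rng.random((20, 20)) < 0.5
        x = np.zeros((20 + 2 * pad, 20 + 2 * pad), dtype=bool)
        x[pad:-pad, pad:-pad] = core
        lhs = dilate(x, se)
        rhs = ~erode(~x, se.reflected())
        np.testing.assert_array_equal(
            lhs[pad:-pad, pad:-pad], rhs[pad:-pad, pad:-pad]
        )


@pytest.mark.parametrize("se_name", ["cross3", "square3"])
def test_morphology_cross_checked_against_scipy(rng, se_name):
    from scipy import ndimage

    se = StructuringElement.named(se_name)
    footprint = np.zeros((3, 3), dtype=bool)
    for dr, dc in se.offsets:
        footprint[dr + 1, dc + 1] = True
    mask = rng.random((20, 20)) < 0.5
    np.testing.assert_array_equal(
        erode(mask, se),
        ndimage.binary_erosion(mask, structure=footprint, border_value=0),
    )
    np.testing.assert_array_equal(
        dilate(mask, se),
        ndimage.binary_dilation(mask, structure=footprint, border_value=0),
    )


def test_opening_removes_single_pixel_speckle():
    mask = np.zeros((9, 9), dtype=bool)
    mask[1, 1] = True              # isolated noise pixel
    mask[4:8, 4:8] = True          # a real component
    cleaned = opening(mask, SQUARE)
    assert not cleaned[1, 1]
    assert cleaned[5, 5]


# --- full localization ------------------------------------------------------

def test_scar_pipeline_no_arcs_yields_empty_mask():
    img, myo, _ = generate_phantom(PhantomSpec(seed=11, scar_arcs=()))
    assert not scar_pipeline(img, myo).any()


def test_scar_pipeline_recovers_ground_truth(small_phantom):
    img, myo, scar = small_phantom
    candidate = scar_pipeline(img, myo)
    assert dice(candidate, scar) >= 0.8
    assert not (candidate & ~myo).any()


def test_dice_degenerate_cases():
    a = np.zeros((3, 3), dtype=bool)
    assert dice(a, a) == 1.0
    b = a.copy()
    b[0, 0] = True
    assert dice(a, b) == 0.0
    assert dice(b, b) == 1.0
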