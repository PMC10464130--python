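"""LBP codes, riu2 mapping, feature histograms, Wasserstein distance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import wasserstein_distance

from radscar.errors import (
    ImageTooSmallError,
    LBPCodeRangeError,
    MissingLabelError,
    NeighborCountError,
    UnnormalizedHistogramError,
)
from radscar.features import (
    FeatureVector,
    class_mean_histogram,
    lbp_code,
    lbp_feature,
    riu2_label,
    wasserstein_1d,
    NEIGHBOR_OFFSETS,
)


# --- lbp_code ---------------------------------------------------------------

def test_code_extremes():
    assert lbp_code(5.0, [5.0] * 8) == 255  # ties set the bit
    assert lbp_code(5.0, [4.9] * 8) == 0


def test_code_matches_bit_enumeration_oracle(rng):
    for _ in range(1000):
        center = rng.normal()
        neighbors = rng.normal(size=8)
        expected = sum(
            2**i for i in range(8) if neighbors[i] >= center
        )
        assert lbp_code(center, neighbors) == expected


def test_code_requires_eight_neighbors():
    with pytest.raises(NeighborCountError):
        lbp_code(0.0, [1.0] * 7)


# --- riu2 mapping -----------------------------------------------------------

def _transitions(code):
    bits = [(code >> i) & 1 for i in range(8)]
    return sum(bits[i] != bits[(i + 1) % 8] for i in range(8))


def test_riu2_examples():
    assert riu2_label(0) == 0
    assert riu2_label(255) == 8
    assert riu2_label(0b00000101) == 9  # two isolated bits, 4 transitions


def test_riu2_exhaustive_against_transition_oracle():
    uniform = 0
    for code in range(256):
        expected = bin(code).count("1") if _transitions(code) <= 2 else 9
        assert riu2_label(code) == expected
        if _transitions(code) <= 2:
            uniform += 1
    assert uniform == 58


def test_riu2_invariant_under_circular_rotation():
    for code in range(256):
        for r in range(8):
            rotated = ((code << r) | (code >> (8 - r))) & 0xFF
            assert riu2_label(rotated) == riu2_label(code)


def test_riu2_range_check():
    with pytest.raises(LBPCodeRangeError):
        riu2_label(256)


# --- lbp_feature ------------------------------------------------------------

def _feature_oracle(image):
    """Naive double loop over interior pixels."""
    h, w = image.shape
    hist = np.zeros(10)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            nbs = [image[r + dr, c + dc] for dr, dc in NEIGHBOR_OFFSETS]
            hist[riu2_label(lbp_code(image[r, c], nbs))] += 1
    return hist / hist.sum()


def test_constant_image_codes_to_bin_eight():
    f = lbp_feature(np.full((6, 6), 42.0))
    expected = np.zeros(10)
    expected[8] = 1.0
    np.testing.assert_allclose(f.bins, expected)


def test_feature_matches_double_loop_oracle(rng):
    for _ in range(5):
        img = rng.normal(size=(10, 10))
        f = lbp_feature(img)
        np.testing.assert_allclose(f.bins, _feature_oracle(img), atol=1e-12)
        assert f.bins.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(f.bins >= 0)


@pytest.mark.parametrize("transform", [
    lambda x: 2 * x + 7,
    lambda x: x**3,
], ids=["affine", "cubic"])
def test_feature_invariant_under_monotone_transforms(rng, transform):
    img = rng.uniform(0.1, 10.0, size=(12, 12))  # positive, so x**3 is monotone
    np.testing.assert_allclose(
        lbp_feature(img).bins, lbp_feature(transform(img)).bins, atol=0
    )


def test_feature_requires_3x3():
    with pytest.raises(ImageTooSmallError):
        lbp_feature(np.zeros((2, 5)))


# --- class aggregation ------------------------------------------------------

def _fv(bins, label):
    return FeatureVector(bins=np.asarray(bins, dtype=float), label=label)


def test_class_mean_histogram_basics(rng):
    one_hot = np.eye(10)[3]
    assert np.array_equal(
        class_mean_histogram([_fv(one_hot, "scar")], "scar"), one_hot
    )
    fvs = [_fv(one_hot, "scar"), _fv(one_hot, "scar")]
    assert np.array_equal(class_mean_histogram(fvs, "scar"), one_hot)
    with pytest.raises(MissingLabelError):
        class_mean_histogram(fvs, "normal")


def test_class_mean_matches_loop_oracle(rng):
    fvs = []
    for i in range(7):
        b = rng.random(10)
        fvs.append(_fv(b / b.sum(), "scar" if i % 2 else "normal"))
    got = class_mean_histogram(fvs, "scar")
    rows = [f.bins for f in fvs if f.label == "scar"]
    expected = sum(rows) / len(rows)
    np.testing.assert_allclose(got, expected, atol=1e-12)
    assert got.sum() == pytest.approx(1.0, abs=1e-9)


# --- wasserstein ------------------------------------------------------------

def _random_hist(rng):
    h = rng.random(10)
    return h / h.sum()


def test_wasserstein_identity_and_extremes():
    p = np.eye(10)[0]
    q = np.eye(10)[9]
    assert wasserstein_1d(p, p) == 0.0
    assert wasserstein_1d(p, q) == pytest.approx(9.0)


def test_wasserstein_matches_scipy_and_quantile_coupling(rng):
    bins = np.arange(10.0)
    for _ in range(50):
        p, q = _random_hist(rng), _random_hist(rng)
        got = wasserstein_1d(p, q)
        # independent oracle 1: scipy's quantile-coupling implementation
        assert got == pytest.approx(
            wasserstein_distance(bins, bins, p, q), abs=1e-9
        )
        # independent oracle 2: CDF definition written out longhand
        cdf_diff = 0.0
        cp = cq = 0.0
        for k in range(10):
            cp += p[k]
            cq += q[k]
            cdf_diff += abs(cp - cq)
        assert got == pytest.approx(cdf_diff, abs=1e-9)


def test_wasserstein_metric_axioms(rng):
    for _ in range(100):
        p, q, r = (_random_hist(rng) for _ in range(3))
        dpq = wasserstein_1d(p, q)
        assert dpq >= 0
        assert 0 <= dpq <= 9
        assert dpq == pytest.approx(wasserstein_1d(q, p), abs=1e-12)
        assert wasserstein_1d(p, r) <= dpq + wasserstein_1d(q, r) + 1e-9


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_wasserstein_zero_iff_identical(seed):
    rng = np.random.default_rng(seed)
    p = _random_hist(rng)
    q = _random_hist(rng)
    if np.allclose(p, q, atol=0):
        assert wasserstein_1d(p, q) == 0.0
    else:
        assert wasserstein_1d(p, q) > 0.0


def test_wasserstein_rejects_unnormalized():
    with pytest.raises(UnnormalizedHistogramError):
        wasserstein_1d(np.ones(10), np.eye(10)[0])
    with pytest.raises(UnnormalizedHistogramError):
        bad = np.eye(10)[0].copy()
        bad[1] = -0.1
        bad[0] = 1.1
        wasserstein_1d(bad, np.eye(10)[0])
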