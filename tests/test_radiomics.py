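"""Radiomics core: worked examples, filter identities, oracle equivalence
and structural invariants of the texture machinery."""

import numpy as np
import pytest

from glioscan.image import ImageVolume
from glioscan.radiomics import (
    FilterBankConfig,
    direction_offsets,
    discretize,
    derived_images,
    extract_features,
    first_order_features,
    glcm_matrix,
    glszm_features,
    glszm_matrix,
    log_filter,
    shape_features,
    texture_features,
    texture_matrices,
    wavelet_decompose,
)
from glioscan.radiomics.discretize import DiscretizedImage
from glioscan.radiomics.texture import _glcm_single

from oracles import oracle_all_features

# ------------------------------------------------------------- discretization


def test_discretize_one_value_per_bin():
    vals = np.array([0.0, 1.0, 2.0, 3.0]).reshape(4, 1, 1)
    d = discretize(vals, np.ones_like(vals, bool), n_bins=4)
    assert list(d.levels.ravel()) == [1, 2, 3, 4]


def test_discretize_constant_region_single_level():
    vals = np.full((3, 3, 2), 7.0)
    d = discretize(vals, np.ones_like(vals, bool), n_bins=16)
    assert d.n_levels == 1 and set(d.in_mask_levels) == {1}


def test_discretize_uniform_occupancy():
    rng = np.random.default_rng(0)
    vals = rng.random((50, 50, 40))
    d = discretize(vals, np.ones_like(vals, bool), n_bins=32)
    counts = np.bincount(d.in_mask_levels, minlength=33)[1:]
    from scipy.stats import chisquare

    assert chisquare(counts).pvalue > 0.01


def test_discretize_empty_mask_errors():
    with pytest.raises(ValueError):
        discretize(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), 4)


# ------------------------------------------------------------------ filters


def test_log_annihilates_constants_and_ramps():
    const = ImageVolume(np.full((40, 20, 12), 5.0), (1, 1, 1))
    assert np.abs(log_filter(const, 2.0).values).max() < 1e-10
    ramp = ImageVolume(np.tile(np.arange(80.0)[:, None, None], (1, 40, 40)), (1, 1, 1))
    out = log_filter(ramp, 2.0).values
    interior = out[20:-20, 18:-18, 18:-18]  # beyond the truncated kernel radius
    assert np.abs(interior).max() < 1e-9


def test_log_scale_selectivity():
    # a Gaussian blob of scale s responds most strongly (most negatively)
    # at the matched filter scale among {s/2, s, 2s}
    s = 4.0
    ax = np.arange(48) - 24.0
    az = np.arange(32) - 16.0
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    blob = np.exp(-(X**2 + Y**2 + Z**2) / (2 * s**2))
    img = ImageVolume(blob, (1, 1, 1))
    center = (24, 24, 16)
    responses = {}
    for sig in (s / 2, s, 2 * s):
        # normalize response by sigma^2 (scale-normalized LoG)
        responses[sig] = sig**2 * log_filter(img, sig).values[center]
    assert min(responses, key=lambda k: responses[k]) == s


def test_log_linearity(rng):
    img = ImageVolume(rng.normal(size=(16, 16, 8)), (1.5, 1.5, 3.0))
    a = 3.7
    lhs = log_filter(img.with_values(a * img.values), 2.5).values
    rhs = a * log_filter(img, 2.5).values
    assert np.allclose(lhs, rhs, atol=1e-10)


def test_wavelet_highpass_kills_constants():
    img = ImageVolume(np.full((12, 10, 8), 3.0), (1, 1, 1))
    bands = wavelet_decompose(img)
    for label, sub in bands.items():
        if "H" in label:
            assert np.abs(sub.values).max() < 1e-12, label
    assert np.allclose(bands["LLL"].values, 3.0)


def test_wavelet_impulse_gives_separable_kernel():
    import itertools

    import pywt

    img = np.zeros((16, 16, 16))
    img[8, 8, 8] = 1.0
    bands = wavelet_decompose(ImageVolume(img, (1, 1, 1)))
    w = pywt.Wavelet("coif1")
    lo = np.array(w.dec_lo) / np.sum(w.dec_lo)
    hi = np.array(w.dec_hi) / np.sum(w.dec_lo)
    taps = {"L": lo, "H": hi}
    # oracle: the impulse response must be the separable outer-product kernel
    # (compared as sorted tap products, independent of centring convention)
    for label in ("LLH", "HHH", "LHL"):
        got = np.sort(bands[label].values.ravel())
        expect = np.sort(np.array([
            wi * wj * wl
            for wi, wj, wl in itertools.product(
                taps[label[0]], taps[label[1]], taps[label[2]]
            )
        ] + [0.0] * (img.size - len(lo) ** 3)))
        assert np.allclose(got, expect, atol=1e-12), label


def test_wavelet_linearity(rng):
    img = ImageVolume(rng.normal(size=(10, 10, 6)), (1, 1, 1))
    bands1 = wavelet_decompose(img)
    bands2 = wavelet_decompose(img.with_values(2.5 * img.values))
    for label in bands1:
        assert np.allclose(2.5 * bands1[label].values, bands2[label].values, atol=1e-10)


# --------------------------------------------------------------- first order


def test_first_order_mean_median():
    vals = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
    f, _ = first_order_features(vals, np.ones_like(vals, bool))
    assert f["Mean"] == 2.5 and f["Median"] == 2.5


def test_first_order_constant_region():
    vals = np.full((3, 2, 1), 4.2)
    f, undef = first_order_features(vals, np.ones_like(vals, bool))
    for name in ("Mean", "Median", "10Percentile", "90Percentile"):
        assert f[name] == pytest.approx(4.2)
    assert "Skewness" in undef


def test_first_order_uniformity_hand_computed():
    vals = np.array([1.0, 1, 2, 2, 4, 4]).reshape(6, 1, 1)
    f, _ = first_order_features(vals, np.ones_like(vals, bool), n_bins=4)
    assert f["Uniformity"] == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_first_order_single_voxel_flags_dispersion():
    f, undef = first_order_features(np.array([[[5.0]]]), np.ones((1, 1, 1), bool))
    assert f["Mean"] == 5.0
    assert "Skewness" in undef and "Kurtosis" in undef
    assert np.isfinite(list(f.values())).all()


def test_first_order_permutation_invariance(rng):
    vals = rng.normal(size=(4, 5, 3))
    mask = np.ones_like(vals, bool)
    f1, _ = first_order_features(vals, mask)
    perm = rng.permutation(vals.ravel()).reshape(vals.shape)
    f2, _ = first_order_features(perm, mask)
    assert f1["Mean"] == pytest.approx(f2["Mean"])
    assert f1["Median"] == pytest.approx(f2["Median"])


# --------------------------------------------------------------------- shape


def test_shape_single_voxel_and_cube():
    m = np.zeros((5, 5, 5), bool)
    m[2, 2, 2] = True
    f = shape_features(m, (1, 1, 1))
    assert f["VoxelVolume"] == pytest.approx(1.0)
    m2 = np.zeros((6, 6, 6), bool)
    m2[2:4, 2:4, 2:4] = True
    f2 = shape_features(m2, (1, 1, 1))
    assert f2["VoxelVolume"] == pytest.approx(8.0)


def test_shape_axis_ordering_matches_box():
    m = np.zeros((14, 8, 6), bool)
    m[2:12, 2:6, 2:4] = True  # 10 x 4 x 2 voxel box
    f = shape_features(m, (1, 1, 1))
    assert f["MajorAxisLength"] >= f["MinorAxisLength"] >= f["LeastAxisLength"]
    # PCA oracle on the coordinates
    coords = np.argwhere(m).astype(float)
    eig = np.sort(np.linalg.eigvalsh(np.cov(coords, rowvar=False)))[::-1]
    assert f["MajorAxisLength"] == pytest.approx(4 * np.sqrt(eig[0]))
    assert f["LeastAxisLength"] == pytest.approx(4 * np.sqrt(eig[2]))


# ------------------------------------------------------------- texture: worked


def _dimg2d(arr):
    arr = np.asarray(arr)
    return DiscretizedImage(arr, np.ones_like(arr, bool), int(arr.max()),
                            np.array([0, arr.max()]))


def test_glcm_two_column_slice():
    C = glcm_matrix(_dimg2d([[1, 2], [1, 2]]))
    horiz = C[direction_offsets(2).index((0, 1))]
    assert horiz[0, 1] == pytest.approx(0.5)
    assert horiz[1, 0] == pytest.approx(0.5)
    assert horiz[0, 0] == horiz[1, 1] == 0.0
    f, _ = _glcm_single(horiz)
    assert f["Contrast"] == pytest.approx(1.0, abs=1e-12)
    assert f["DifferenceAverage"] == pytest.approx(1.0, abs=1e-12)


def test_glszm_worked_example():
    P = glszm_matrix(_dimg2d([[1, 1, 2], [2, 2, 3], [3, 3, 3]]))
    # zones: (level 1, size 2), (level 2, size 3), (level 3, size 4)
    assert P.sum() == 3
    assert P[0, 1] == 1 and P[1, 2] == 1 and P[2, 3] == 1
    f, _ = glszm_features(P, 9)
    assert f["LargeAreaLowGrayLevelEmphasis"] == pytest.approx(
        (4 / 1 + 9 / 4 + 16 / 9) / 3, abs=1e-12
    )


def test_constant_volume_degenerate_texture():
    vals = np.full((3, 3, 3), 2.0)
    d = discretize(vals, np.ones_like(vals, bool), 32)
    mats = texture_matrices(d)
    assert mats["glszm"].shape[0] == 1 and mats["glszm"][0, 26] == 1  # one 27-voxel zone
    feats, undef = texture_features(mats)
    assert feats["glcm_Contrast"] == 0.0
    assert "glcm_Correlation" in undef  # single gray level


# ----------------------------------------------------- oracle equivalence


@pytest.mark.parametrize("full_mask", [True, False])
def test_texture_features_match_bruteforce_oracle(rng, full_mask):
    """All five matrix classes agree with naive nested-loop oracles on
    random 5x5x3 discretized images, to 1e-12."""
    from conftest import random_discretized

    for _ in range(8):
        levels, mask = random_discretized(rng, ng=4, full_mask=full_mask)
        ng = int(levels.max())
        d = DiscretizedImage(levels, mask, ng, np.array([0, ng]))
        feats, undef = texture_features(texture_matrices(d))
        expected = oracle_all_features(levels, mask, ng)
        assert set(feats) == set(expected)
        for k, v in expected.items():
            assert feats[k] == pytest.approx(v, rel=1e-12, abs=1e-12), k


# ------------------------------------------------------------ invariants


def test_glcm_symmetry_and_normalization(rng):
    from conftest import random_discretized

    levels, mask = random_discretized(rng, ng=5)
    d = DiscretizedImage(levels, mask, 5, np.array([0, 5]))
    C = glcm_matrix(d)
    for k in range(C.shape[0]):
        assert np.allclose(C[k], C[k].T)
        assert C[k].sum() == pytest.approx(1.0)


def test_angle_averaged_features_rotation_invariant(rng):
    """90-degree in-plane rotation of an isotropic image leaves the
    angle-averaged GLCM/GLRLM features unchanged."""
    levels = rng.integers(1, 5, size=(6, 6, 4))
    mask = np.ones_like(levels, bool)
    rot = np.rot90(levels, axes=(0, 1)).copy()
    f1, _ = texture_features(texture_matrices(
        DiscretizedImage(levels, mask, 4, np.array([0, 4]))))
    f2, _ = texture_features(texture_matrices(
        DiscretizedImage(rot, np.ones_like(rot, bool), 4, np.array([0, 4]))))
    for k in f1:
        if k.startswith(("glcm_", "glrlm_")):
            assert f1[k] == pytest.approx(f2[k], rel=1e-10), k


def test_glszm_zone_sizes_sum_to_voxel_count(rng):
    from conftest import random_discretized

    levels, mask = random_discretized(rng, shape=(6, 5, 4), ng=3, full_mask=False)
    d = DiscretizedImage(levels, mask, 3, np.array([0, 3]))
    P = glszm_matrix(d)
    sizes = np.arange(1, P.shape[1] + 1)
    assert (P * sizes).sum() == mask.sum()


# ------------------------------------------------------------- extraction


def test_extract_features_structure(phantom):
    t1, t2, m1, m2 = phantom
    cfg = FilterBankConfig(log_sigmas_mm=(3.0,), wavelet=True, n_bins=16)
    fx = extract_features(t1, t2, m1, m2, cfg)
    # manifest covers every computed value; grammar check
    assert set(fx.values) == {m["id"] for m in fx.manifest}
    some = "T2_log.sigma.3.0.mm.3D_glszm_LargeAreaLowGrayLevelEmphasis"
    assert some in fx.values
    assert "T1_wavelet.HHH_firstorder_Median" in fx.values
    assert all(np.isfinite(v) for v in fx.values.values())


def test_wavelet_toggle_drops_eight_per_image(phantom):
    """Disabling the wavelet bank removes exactly 8 sub-bands' worth of
    per-image features (manifest arithmetic)."""
    t1, t2, m1, m2 = phantom
    on = extract_features(t1, t2, m1, m2, FilterBankConfig(log_sigmas_mm=(), wavelet=True))
    off = extract_features(t1, t2, m1, m2, FilterBankConfig(log_sigmas_mm=(), wavelet=False))
    n_on = len(on.values) + len(on.undefined)
    n_off = len(off.values) + len(off.undefined)
    per_image = sum(
        1 for m in off.manifest
        if m["modality"] == "T1" and m["filter"] == "original" and m["class"] != "shape"
    ) + sum(1 for k in off.undefined if k.startswith("T1_original") and "shape" not in k)
    assert n_on - n_off == 8 * per_image * 2  # 8 sub-bands x 2 modalities


def test_identical_patients_identical_features(phantom):
    t1, t2, m1, m2 = phantom
    cfg = FilterBankConfig(log_sigmas_mm=(2.0,), wavelet=False)
    a = extract_features(t1, t2, m1, m2, cfg)
    b = extract_features(t1, t2, m1, m2, cfg)
    assert a.values == b.values
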