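"""S-BM3D: distance, matching, shrinkage stages, aggregation, full filter."""

import numpy as np
import pytest

import veinforge as vf
from veinforge.sbm3d import (DenoiserParams, PatchGroup, PixelAggregator,
                             patch_distance, block_match, stage1_llmmse,
                             stage2_wiener, aggregate, sbm3d_denoise,
                             _forward_3d, _inverse_3d, _band_gains,
                             _iter_bands, EPS_AMPLITUDE)


# --- patch distance ----------------------------------------------------------

def test_identical_patches_reach_likelihood_minimum():
    rng = np.random.default_rng(0)
    for L in (1.0, 4.0, 9.5):
        a = rng.random((6, 6)) + 0.1
        expected = a.size * (2 * L - 1) * np.log(2.0)
        assert patch_distance(a, a, looks=L) == pytest.approx(expected, rel=1e-12)


def test_two_pixel_hand_example():
    d = patch_distance(np.array([1.0, 2.0]), np.array([2.0, 1.0]), looks=1.0)
    assert d == pytest.approx(2.0 * np.log(2.5), rel=1e-12)


def test_distance_symmetry_and_termwise_oracle():
    """Matches an independent term-by-term summation, including the prior
    term, and is symmetric under argument swap."""
    rng = np.random.default_rng(1)
    L, gamma = 3.0, 4.0
    for _ in range(200):
        a = rng.random((5, 5)) + 0.05
        b = rng.random((5, 5)) + 0.05
        pa = rng.random((5, 5)) + 0.05
        pb = rng.random((5, 5)) + 0.05
        oracle = 0.0
        for k in range(25):
            x, y = a.flat[k], b.flat[k]
            oracle += (2 * L - 1) * np.log(x / y + y / x)
            u, v = pa.flat[k], pb.flat[k]
            oracle += gamma * (u - v) ** 2 / (u * v)
        d = patch_distance(a, b, pa, pb, looks=L, gamma=gamma)
        assert d == pytest.approx(oracle, abs=1e-10)
        assert patch_distance(b, a, pb, pa, looks=L, gamma=gamma) == pytest.approx(d, abs=1e-10)


def test_distance_input_validation():
    with pytest.raises(ValueError):
        patch_distance(np.ones((2, 2)), np.ones((3, 3)))
    with pytest.raises(ValueError):
        patch_distance(np.ones((2, 2)), np.ones((2, 2)), gamma=1.0)


# --- block matching ----------------------------------------------------------

def _brute_force_group(img, prior, ref, p):
    """Exhaustive stable scan oracle mirroring the documented convention:
    reference first, then the max_group-1 nearest others in scan order."""
    b = p.block_size
    H, W = img.shape
    half = (p.search_window - b) // 2
    r0, c0 = ref
    cand = []
    for r in range(max(0, r0 - half), min(H - b, r0 + half) + 1):
        for c in range(max(0, c0 - half), min(W - b, c0 + half) + 1):
            if (r, c) == (r0, c0):
                continue
            d = patch_distance(img[r0:r0 + b, c0:c0 + b], img[r:r + b, c:c + b],
                               None if prior is None else prior[r0:r0 + b, c0:c0 + b],
                               None if prior is None else prior[r:r + b, c:c + b],
                               looks=p.looks, gamma=p.gamma if prior is not None else 0.0)
            cand.append((d, (r, c)))
    order = np.argsort([d for d, _ in cand], kind="stable")
    kept = [cand[i] for i in order[:p.max_group - 1]]
    locs = [(r0, c0)] + [loc for _, loc in kept]
    return locs


@pytest.mark.parametrize("seed", range(5))
def test_block_match_equals_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    img = rng.random((32, 32)) + 0.05
    p = DenoiserParams(block_size=4, search_window=16, max_group=8,
                       looks=4.0, gamma=0.0)
    for ref in [(5, 7), (0, 0), (28, 28)]:
        group = block_match(img, None, ref, p)
        assert group.member_locations == _brute_force_group(img, None, ref, p)


def test_block_match_with_prior_term_matches_oracle():
    rng = np.random.default_rng(9)
    img = rng.random((24, 24)) + 0.05
    prior = rng.random((24, 24)) + 0.05
    p = DenoiserParams(block_size=4, search_window=12, max_group=8,
                       looks=2.0, gamma=4.0)
    group = block_match(img, prior, (10, 10), p)
    assert group.member_locations == _brute_force_group(img, prior, (10, 10), p)


def test_planted_copies_are_all_grouped():
    rng = np.random.default_rng(2)
    img = rng.random((32, 32)) * 0.2 + 0.4
    motif = rng.random((4, 4)) * 0.5 + 0.3
    for r, c in [(8, 8), (8, 14), (12, 10)]:
        img[r:r + 4, c:c + 4] = motif
    p = DenoiserParams(block_size=4, search_window=16, max_group=8, looks=4.0,
                       gamma=0.0)
    group = block_match(img, None, (8, 8), p)
    locs = set(group.member_locations)
    assert {(8, 8), (8, 14), (12, 10)} <= locs
    assert len(group.member_locations) <= p.max_group
    assert np.all(np.diff(group.distances) >= -1e-12)


def test_reference_outside_image_rejected():
    p = DenoiserParams(block_size=8, search_window=16)
    with pytest.raises(ValueError):
        block_match(np.ones((16, 16)), None, (12, 12), p)


# --- transform & shrinkage ---------------------------------------------------

def test_3d_transform_roundtrip():
    rng = np.random.default_rng(3)
    for G, b in [(16, 8), (8, 4), (1, 8)]:
        st = rng.random((2, G, b, b))
        back = _inverse_3d(_forward_3d(st, "db8", 2), "db8", G)
        np.testing.assert_allclose(back, st, atol=1e-8)


def test_band_gain_predicts_speckle_coefficient_variance():
    """The sigma_n^2 predicted from L matches the empirical per-band
    coefficient variance of pure speckle on a constant image within 5%."""
    rng = np.random.default_rng(4)
    L, c, trials, b = 4.0, 0.6, 2000, 8
    raw = np.sqrt(rng.gamma(L, 1.0 / L, size=(trials, b, b)))
    u = raw / vf.speckle_multiplier_mean(L)
    patches = c * u
    import pywt
    coeffs = pywt.swtn(patches, "db8", level=2, axes=(-2, -1),
                       trim_approx=True, norm=True)
    gains = _band_gains("db8", 2, b)
    su2 = vf.speckle_multiplier_var(L)
    for key, arr in _iter_bands(coeffs):
        if key == ("approx",):
            continue  # approx band mixes in the deterministic mean
        predicted = su2 * c * c * gains[key]
        empirical = arr.var()
        assert empirical == pytest.approx(predicted, rel=0.05)


def test_stage1_is_identity_without_noise():
    """sigma_n^2 = 0 (infinite looks) leaves every coefficient unshrunk."""
    rng = np.random.default_rng(5)
    img = rng.random((32, 32)) + 0.1
    p = DenoiserParams(block_size=8, search_window=16, max_group=8,
                       looks=np.inf, gamma=0.0)
    group = block_match(img, None, (10, 10), p)
    out = stage1_llmmse(group, p)
    np.testing.assert_allclose(out, group.stack[:out.shape[0]], atol=1e-8)


def test_stage1_rejects_empty_group():
    p = DenoiserParams()
    g = PatchGroup((0, 0), [(0, 0)], np.ones((1, 8, 8)), [0.0])
    g.stack = np.empty((0, 8, 8))
    with pytest.raises(ValueError):
        stage1_llmmse(g, p)


def test_stage2_limits():
    rng = np.random.default_rng(6)
    img = rng.random((32, 32)) + 0.1
    p = DenoiserParams(block_size=8, search_window=16, max_group=8, looks=4.0,
                       gamma=0.0)
    group = block_match(img, None, (12, 12), p)
    stack = group.stack[:8]
    # <V^2> = 0: prior equals noisy, filter passes the data through
    out = stage2_wiener(group, stack.copy(), p)
    np.testing.assert_allclose(out, stack, atol=1e-8)
    # zero prior: output is identically zero
    out0 = stage2_wiener(group, np.zeros_like(stack), p)
    np.testing.assert_allclose(out0, 0.0, atol=1e-12)


def test_wiener_scalar_form():
    """X'^2 = 1, <V^2> = 1, Z = 2 shrinks to 1 (the printed substitution)."""
    xp2, v2, z = 1.0, 1.0, 2.0
    assert xp2 / (xp2 + v2) * z == pytest.approx(1.0)


# --- aggregation -------------------------------------------------------------

def test_aggregator_weighted_mean_conventions():
    agg = PixelAggregator(shape=(4, 4))
    agg.add_patch((0, 0), np.full((2, 2), 2.0), 1.0)
    agg.add_patch((0, 0), np.full((2, 2), 4.0), 3.0)
    agg.add_patch((2, 2), np.full((2, 2), 0.7), 5.0)
    agg.add_patch((0, 2), np.full((2, 2), 1.3), 1.0)
    agg.add_patch((2, 0), np.full((2, 2), 0.2), 0.5)
    out = aggregate(agg, (4, 4))
    assert out[0, 0] == pytest.approx(3.5)      # {2,4} with weights {1,3}
    assert out[2, 2] == pytest.approx(0.7)      # single estimate passthrough
    assert out[0, 2] == pytest.approx(1.3)


def test_aggregator_flags_uncovered_pixels():
    agg = PixelAggregator(shape=(4, 4))
    agg.add_patch((0, 0), np.ones((2, 2)), 1.0)
    with pytest.raises(ValueError):
        aggregate(agg, (4, 4))
    with pytest.raises(ValueError):
        agg.add_patch((0, 0), np.ones((2, 2)), -1.0)


# --- full filter -------------------------------------------------------------

def test_denoise_constant_image_fixed_point():
    c = np.full((64, 64), 0.5)
    out = sbm3d_denoise(c, DenoiserParams(looks=4.0))
    np.testing.assert_allclose(out, c, atol=1e-6)


def test_denoise_is_deterministic_and_shape_preserving():
    rng = np.random.default_rng(7)
    img = np.clip(rng.random((48, 48)), 0.05, 1.0)
    p = DenoiserParams(block_size=8, search_window=16, max_group=8, looks=4.0)
    a = sbm3d_denoise(img, p)
    b = sbm3d_denoise(img, p)
    np.testing.assert_array_equal(a, b)
    assert a.shape == img.shape
    assert np.all(np.isfinite(a))


def test_denoise_improves_psnr(phantom128):
    from skimage.metrics import peak_signal_noise_ratio as psnr
    clean, noisy = phantom128["clean"], phantom128["noisy"]
    den = np.clip(sbm3d_denoise(noisy, DenoiserParams(looks=4.0)), 0, 1)
    assert psnr(clean, den, data_range=1) > psnr(clean, noisy, data_range=1)


def test_single_stage_output_differs_from_two_stage():
    rng = np.random.default_rng(8)
    img = np.clip(0.5 + 0.1 * rng.standard_normal((48, 48)), 0.05, 1.0)
    p = DenoiserParams(block_size=8, search_window=16, max_group=8, looks=4.0)
    one = sbm3d_denoise(img, p, single_stage=True)
    two = sbm3d_denoise(img, p)
    assert not np.allclose(one, two)


def test_params_validation():
    with pytest.raises(ValueError):
        DenoiserParams(block_size=16, search_window=8).validate()
    with pytest.raises(ValueError):
        DenoiserParams(max_group=6).validate()
    with pytest.raises(ValueError):
        DenoiserParams(looks=0.0).validate()
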