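"""Pre-processing: projection, background, IsoData, particles — with
brute-force oracles for the threshold and the labeling."""

import numpy as np
import pytest

import sarcoscan as sc
from _oracles import flood_fill_label, isodata_fixed_points


def img(arr, p=40.0, channel="t"):
    return sc.Image2D(np.asarray(arr, dtype=float), p, channel)


# ---------------------------------------------------------------------------
# max_project
# ---------------------------------------------------------------------------

def test_max_project_single_slice_identity():
    a = img(np.arange(12.0).reshape(3, 4))
    np.testing.assert_array_equal(sc.max_project([a]).pixels, a.pixels)


def test_max_project_disjoint_supports_union_and_permutation_invariance():
    a = np.zeros((4, 4)); a[0, 0] = 3.0
    b = np.zeros((4, 4)); b[2, 2] = 5.0
    c = np.zeros((4, 4)); c[0, 0] = 1.0
    slices = [img(a), img(b), img(c)]
    proj = sc.max_project(slices).pixels
    assert proj[0, 0] == 3.0 and proj[2, 2] == 5.0 and proj.sum() == 8.0
    proj_rev = sc.max_project(slices[::-1]).pixels
    np.testing.assert_array_equal(proj, proj_rev)


def test_max_project_shape_mismatch():
    with pytest.raises(sc.ParameterError):
        sc.max_project([img(np.zeros((2, 2))), img(np.zeros((3, 3)))])


# ---------------------------------------------------------------------------
# subtract_background
# ---------------------------------------------------------------------------

def test_constant_image_subtracts_to_zero():
    with pytest.warns(UserWarning, match="ROI likely contains signal"):
        out = sc.subtract_background(img(np.full((8, 8), 50.0)), (0, 0, 4, 4))
    assert np.all(out.pixels == 0.0)
    assert out.provenance["background_subtracted"] == 50.0


def test_band_on_background_subtraction():
    pix = np.full((8, 16), 50.0)
    pix[:, 6:10] = 150.0
    out = sc.subtract_background(img(pix), (0, 0, 4, 8))
    assert np.all(out.pixels[:, 6:10] == 100.0)
    assert np.all(out.pixels[:, :4] == 0.0)


def test_subtraction_monotone_in_roi_mean():
    pix = np.full((8, 16), 50.0)
    pix[:, 6:10] = 150.0
    bg_only = sc.subtract_background(img(pix), (0, 0, 4, 8))
    with pytest.warns(UserWarning):
        over_band = sc.subtract_background(img(pix), (6, 0, 4, 8))
    assert (
        over_band.provenance["background_subtracted"]
        > bg_only.provenance["background_subtracted"]
    )
    assert over_band.pixels.sum() < bg_only.pixels.sum()


def test_roi_outside_image_raises():
    with pytest.raises(sc.ParameterError, match="outside"):
        sc.subtract_background(img(np.zeros((8, 8))), (6, 6, 4, 4))


def test_auto_roi_finds_darkest_tile():
    pix = np.full((100, 100), 10.0)
    pix[60:80, 60:80] = 0.0
    x, y, w, h = sc.auto_background_roi(img(pix), tile=16)
    assert 60 <= x and x + w <= 80 and 60 <= y and y + h <= 80


# ---------------------------------------------------------------------------
# isodata_threshold
# ---------------------------------------------------------------------------

def test_symmetric_two_level_image_thresholds_at_midpoint():
    pix = np.concatenate([np.zeros(500), np.full(500, 100.0)]).reshape(20, 50)
    assert sc.isodata_threshold(img(pix)) == pytest.approx(50.0, abs=100 / 256)


def test_constant_image_is_degenerate():
    with pytest.raises(sc.DegenerateImageError):
        sc.isodata_threshold(img(np.full((8, 8), 7.0)))


def test_isodata_matches_exhaustive_fixed_point_scan():
    """100 random 8-bit images: iterative threshold lands on the fixed point
    found by scanning all 256 candidate thresholds."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        # bimodal mixture with random separation and weights
        n_lo = int(rng.integers(200, 3800))
        lo = rng.normal(rng.uniform(20, 80), rng.uniform(2, 15), n_lo)
        hi = rng.normal(rng.uniform(120, 230), rng.uniform(2, 25), 4096 - n_lo)
        pix = np.clip(np.concatenate([lo, hi]), 0, 255).astype(np.uint8)
        pix = pix.reshape(64, 64).astype(float)
        if pix.max() == pix.min():
            continue
        t = sc.isodata_threshold(img(pix))
        candidates = isodata_fixed_points(pix)
        binw = (pix.max() - pix.min()) / 256
        assert candidates, "no discrete fixed point found"
        assert min(abs(t - c) for c in candidates) <= binw, (t, candidates)


# ---------------------------------------------------------------------------
# binarize
# ---------------------------------------------------------------------------

def test_binarize_extremes_and_monotonicity():
    rng = np.random.default_rng(0)
    pix = rng.uniform(0, 1, (32, 32))
    image = img(pix)
    assert not sc.binarize(image, pix.max()).pixels.any()
    assert sc.binarize(image, pix.min() - 1).pixels.all()
    counts = [sc.binarize(image, t).pixels.sum() for t in np.linspace(0, 1, 11)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# analyze_particles
# ---------------------------------------------------------------------------

def mask_of(arr):
    return sc.BinaryMask(np.asarray(arr, dtype=bool), 40.0)


def test_two_squares_areas_and_outlines():
    m = np.zeros((10, 12), dtype=bool)
    m[1:4, 1:4] = True
    m[5:8, 7:10] = True
    ps = sc.analyze_particles(mask_of(m), min_area_px=1)
    assert len(ps) == 2
    for part in ps.particles:
        assert part.area_px == 9
        assert part.outline_pixels.shape[0] == 8  # 3x3 square: all but center


def test_diagonal_pixels_are_one_particle():
    m = np.zeros((4, 4), dtype=bool)
    m[1, 1] = m[2, 2] = True
    ps = sc.analyze_particles(mask_of(m), min_area_px=1)
    assert len(ps) == 1


def test_area_filter_and_label_contiguity():
    rng = np.random.default_rng(7)
    m = rng.uniform(size=(48, 48)) < 0.35
    ps = sc.analyze_particles(mask_of(m), min_area_px=4)
    labels = [p.label for p in ps.particles]
    assert labels == list(range(1, len(labels) + 1))
    assert all(p.area_px >= 4 for p in ps.particles)
    # particle count is non-increasing in min_area
    more = sc.analyze_particles(mask_of(m), min_area_px=1)
    assert len(more) >= len(ps)


def test_labeling_matches_flood_fill_oracle():
    """50 random masks: partition identical to a BFS flood fill, and every
    outline pixel touches background through a 4-neighbor."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        m = rng.uniform(size=(32, 32)) < rng.uniform(0.25, 0.55)
        ps = sc.analyze_particles(mask_of(m), min_area_px=1)
        oracle = flood_fill_label(m)
        impl = ps.labels
        assert (impl > 0).sum() == (oracle > 0).sum() == m.sum()
        # same partition up to label permutation: the label pairs must be
        # in bijection
        pairs = set(zip(impl[m].tolist(), oracle[m].tolist()))
        assert len(pairs) == len({a for a, _ in pairs}) == len({b for _, b in pairs})
        # outline correctness under 4-connectivity with border as background
        padded = np.pad(m, 1)
        for part in ps.particles:
            for r, c in part.outline_pixels:
                neigh = [
                    padded[r, c + 1],
                    padded[r + 2, c + 1],
                    padded[r + 1, c],
                    padded[r + 1, c + 2],
                ]
                assert not all(neigh)


# ---------------------------------------------------------------------------
# preprocess_channel
# ---------------------------------------------------------------------------

def test_clean_channel_particle_count_matches_zdisc_count(clean_image):
    res = sc.preprocess_channel(clean_image.channel("zdisc"))
    assert len(res.particles) == clean_image.ground_truth.centers_nm.size


def test_preprocess_is_deterministic(default_image):
    a = sc.preprocess_channel(default_image.channel("zdisc"))
    b = sc.preprocess_channel(default_image.channel("zdisc"))
    assert a.threshold == b.threshold
    np.testing.assert_array_equal(a.particles.labels, b.particles.labels)


def test_binarizing_a_binary_image_reproduces_it(clean_image):
    res = sc.preprocess_channel(clean_image.channel("zdisc"))
    as_img = sc.Image2D(res.mask.pixels.astype(float), res.mask.pixel_size_nm, "m")
    again = sc.binarize(as_img, 0.5)
    np.testing.assert_array_equal(again.pixels, res.mask.pixels)


def test_zero_background_input_mask_unchanged_by_subtraction(clean_image):
    """On an image whose background is exactly zero, skipping background
    subtraction yields the identical mask."""
    ch = clean_image.channel("zdisc")
    with_sub = sc.preprocess_channel(ch, roi="auto")
    without = sc.preprocess_channel(ch, roi=None)
    np.testing.assert_array_equal(with_sub.mask.pixels, without.mask.pixels)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=100, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_isodata_threshold_lies_between_class_means(seed):
    """For any non-degenerate image the threshold separates the two class
    means: mean(values <= t) <= t <= mean(values > t) (up to one bin)."""
    rng = np.random.default_rng(seed)
    pix = rng.normal(rng.uniform(0, 100), rng.uniform(1, 50), (16, 16))
    if pix.max() == pix.min():
        return
    t = sc.isodata_threshold(img(pix))
    binw = (pix.max() - pix.min()) / 256
    lo = pix[pix <= t]
    hi = pix[pix > t]
    if lo.size and hi.size:
        assert lo.mean() - binw <= t <= hi.mean() + binw
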