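"""Channel-difference thresholding: worked fixtures, oracles and set laws."""

import warnings

import numpy as np
import pytest

from c2fseg import labelgen as L


def two_level_image(size=16):
    """Noiseless image whose normalized G-R difference is exactly 0.5 on the
    foreground disc and -0.1 on the background (channel maxima attained)."""
    img = np.zeros((size, size, 3), dtype=np.uint8)
    yy, xx = np.ogrid[:size, :size]
    fg = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= (size // 4) ** 2
    img[..., 0] = np.where(fg, 100, 200)  # R: fg 0.5, bg 1.0 after /max
    img[..., 1] = np.where(fg, 200, 180)  # G: fg 1.0, bg 0.9 after /max
    return img, fg.astype(np.uint8)


# -- normalisation and differences -----------------------------------------

def test_normalize_channel_scales_by_max():
    img = np.zeros((2, 2, 3), dtype=np.uint8)
    img[..., 1] = [[200, 100], [50, 0]]
    g = L.normalize_channel(img, "G")
    assert np.allclose(g, [[1.0, 0.5], [0.25, 0.0]])


def test_normalize_constant_and_zero_channels():
    img = np.full((3, 3, 3), 7, dtype=np.uint8)
    assert np.all(L.normalize_channel(img, "R") == 1.0)
    img[..., 2] = 0
    assert np.all(L.normalize_channel(img, "B") == 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_channel_diff_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, (9, 9, 3)).astype(np.uint8)
    for a, b in L.ORDERED_PAIRS:
        assert np.array_equal(L.channel_diff(img, (a, b)), -L.channel_diff(img, (b, a)))


def test_grayscale_diffs_vanish():
    v = np.tile(np.arange(8, dtype=np.uint8)[:, None], (1, 8))
    img = np.stack([v, v, v], axis=-1)
    for pair in L.ORDERED_PAIRS:
        assert np.all(L.channel_diff(img, pair) == 0.0)


def test_threshold_diff_ties_and_extremes():
    diff = np.array([[0.5, 0.05], [0.5, -0.1]])
    assert np.array_equal(L.threshold_diff(diff, 0.1), [[1, 0], [1, 0]])
    assert np.array_equal(L.threshold_diff(diff, 0.5), [[1, 0], [1, 0]])  # tie -> fg
    assert np.all(L.threshold_diff(diff, -1.0) == 1)
    assert np.all(L.threshold_diff(diff, 1.01) == 0)


@pytest.mark.parametrize("seed", range(5))
def test_threshold_monotone_in_alpha(seed):
    rng = np.random.default_rng(seed)
    diff = rng.uniform(-1, 1, (12, 12))
    prev = None
    for alpha in np.linspace(-1, 1, 9):
        cur = L.threshold_diff(diff, alpha)
        if prev is not None:
            assert np.all(cur <= prev)  # growing alpha never adds pixels
        prev = cur


# -- MGRL masking -----------------------------------------------------------

def test_mask_with_mgrl_and_idempotence():
    p = np.array([[1, 0], [1, 0]], dtype=np.uint8)
    c = np.array([[1, 1], [0, 0]], dtype=np.uint8)
    out = L.mask_with_mgrl(p, c)
    assert np.array_equal(out, [[1, 0], [0, 0]])
    assert np.array_equal(L.mask_with_mgrl(out, c), out)
    assert np.all(L.mask_with_mgrl(p, np.zeros_like(c)) == 0)
    assert np.array_equal(L.mask_with_mgrl(p, np.ones_like(c)), p)
    with pytest.raises(ValueError, match="shape"):
        L.mask_with_mgrl(p, np.zeros((3, 3)))


# -- CDTL on the worked fixture ---------------------------------------------

def test_cdtl_exact_on_two_level_image():
    img, fg = two_level_image()
    mgrl = np.zeros_like(fg)
    mgrl[2:14, 2:14] = 1  # rough label strictly containing the disc
    mask, sel = L.make_cdtl(img, mgrl, ("G", "R"), alpha=0.1)
    assert np.array_equal(mask, fg & mgrl)
    assert np.array_equal(mask, fg)  # disc lies inside the MGRL


def test_cdtl_auto_alpha_between_margins():
    img, fg = two_level_image()
    mgrl = np.zeros_like(fg)
    mgrl[2:14, 2:14] = 1
    mask, sel = L.make_cdtl(img, mgrl, ("G", "R"), alpha="auto")
    assert -0.1 < sel.alpha < 0.5 or sel.alpha == 0.5  # ties count as foreground
    assert np.array_equal(mask, fg)


def test_cdtl_empty_and_multiclass_errors():
    img, _ = two_level_image()
    empty = np.zeros(img.shape[:2], dtype=np.uint8)
    mask, _ = L.make_cdtl(img, empty)
    assert not mask.any()
    multi = empty.copy()
    multi[0, 0], multi[5, 5] = 1, 2
    with pytest.raises(ValueError, match="gcdt"):
        L.make_cdtl(img, multi)


# -- distance base ----------------------------------------------------------

def brute_force_base(region, cut=0.7):
    """Per-pixel nearest-background search + flood-fill components."""
    h, w = region.shape
    dist = np.zeros((h, w))
    bg = [(i, j) for i in range(h) for j in range(w) if not region[i, j]]
    for i in range(h):
        for j in range(w):
            if region[i, j]:
                if bg:
                    dist[i, j] = min(np.hypot(i - bi, j - bj) for bi, bj in bg)
                else:
                    dist[i, j] = 1.0
    # connected components via BFS (4-connectivity, as scipy's default)
    comp = -np.ones((h, w), dtype=int)
    n = 0
    for i in range(h):
        for j in range(w):
            if region[i, j] and comp[i, j] < 0:
                stack = [(i, j)]
                comp[i, j] = n
                while stack:
                    ci, cj = stack.pop()
                    for ni, nj in ((ci - 1, cj), (ci + 1, cj), (ci, cj - 1), (ci, cj + 1)):
                        if 0 <= ni < h and 0 <= nj < w and region[ni, nj] and comp[ni, nj] < 0:
                            comp[ni, nj] = n
                            stack.append((ni, nj))
                n += 1
    base = np.zeros((h, w), dtype=np.uint8)
    for c in range(n):
        sel = comp == c
        base[sel] = (dist[sel] / dist[sel].max()) >= cut
    return base


@pytest.mark.parametrize("seed", range(4))
def test_distance_base_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    region = (rng.uniform(size=(14, 14)) < 0.45)
    mgrl = region.astype(np.uint8)
    if not region.any():
        pytest.skip("empty draw")
    got = L.distance_base(mgrl, 1)
    assert np.array_equal(got, brute_force_base(region))


def test_distance_base_disk_and_degenerates():
    size = 25
    yy, xx = np.ogrid[:size, :size]
    disk = ((yy - 12) ** 2 + (xx - 12) ** 2 <= 100).astype(np.uint8)
    base = L.distance_base(disk, 1)
    assert base.any()
    assert np.all(disk[base > 0] == 1)  # base inside the region
    assert np.array_equal(base, brute_force_base(disk.astype(bool)))
    single = np.zeros((5, 5), dtype=np.uint8)
    single[2, 2] = 1
    assert np.array_equal(L.distance_base(single, 1), single)
    with pytest.warns(UserWarning, match="absent"):
        empty = L.distance_base(np.zeros((4, 4), dtype=np.uint8), 1)
    assert not empty.any()


# -- candidate scoring and GCDT ---------------------------------------------

def test_score_candidate():
    a = np.zeros((3, 3), dtype=np.uint8)
    b = np.zeros((3, 3), dtype=np.uint8)
    assert L.score_candidate(a, b) == 0.0  # both empty: no evidence
    a[0, :2] = 1
    assert L.score_candidate(a, a) == 1.0
    b[2, :] = 1
    assert L.score_candidate(a, b) == 0.0  # disjoint
    b[:] = 0
    b[0, 0], b[0, 2], b[1, 0] = 1, 1, 1  # |cap|=1... construct |cap|=2,|cup|=5
    a[:] = 0
    a[0, 0], a[0, 1], a[0, 2], a[1, 1] = 1, 1, 1, 1
    assert L.score_candidate(a, b) == pytest.approx(2 / 5)


def gcdt_oracle(image, mgrl, alpha_grid, pairs):
    """Independent exhaustive search with per-pixel IOU counting."""
    selections = {}
    masks = {}
    for k in sorted(int(v) for v in np.unique(mgrl) if v):
        region = mgrl == k
        base = brute_force_base(region)
        best = (-1.0, None, None, None)
        for pair in pairs:
            d = L.channel_diff(image, pair)
            for alpha in alpha_grid:
                cand = (d >= alpha) & region
                inter = np.count_nonzero(cand & (base > 0))
                union = np.count_nonzero(cand | (base > 0))
                s = inter / union if union else 0.0
                if s > best[0]:
                    best = (s, pair, float(alpha), cand)
        selections[k] = best[:3]
        masks[k] = best[3]
    return selections, masks


@pytest.mark.parametrize("seed", range(3))
def test_gcdt_matches_exhaustive_oracle_small(seed):
    from c2fseg.synthgen import gen_pair_separable

    (sample, _expected), = gen_pair_separable(1, image_size=32, n_classes=2, seed=seed)
    grid = L.DEFAULT_ALPHA_GRID
    out, sels = L.gcdt(sample.image, sample.mgrl, grid)
    oracle_sel, oracle_masks = gcdt_oracle(sample.image, sample.mgrl, grid, L.ORDERED_PAIRS)
    for sel in sels:
        score, pair, alpha = oracle_sel[sel.class_id]
        assert sel.pair == pair and sel.alpha == pytest.approx(alpha)
        assert sel.score == pytest.approx(score)
        assert 0.0 <= sel.score <= 1.0


def test_gcdt_single_class_agrees_with_auto_cdtl():
    img = np.zeros((16, 16, 3), dtype=np.uint8)
    yy, xx = np.ogrid[:16, :16]
    fg = (yy - 8) ** 2 + (xx - 8) ** 2 <= 16
    img[..., 0] = np.where(fg, 100, 200)
    img[..., 1] = np.where(fg, 200, 180)
    mgrl = np.zeros((16, 16), dtype=np.uint8)
    mgrl[3:14, 3:14] = 1
    out, sels = L.gcdt(img, mgrl)
    cdtl, sel = L.make_cdtl(img, mgrl, sels[0].pair, alpha="auto")
    assert np.array_equal(out, cdtl)


def test_gcdt_subset_law_and_empty_class():
    rng = np.random.default_rng(5)
    img = rng.integers(0, 256, (20, 20, 3)).astype(np.uint8)
    mgrl = np.zeros((20, 20), dtype=np.uint8)
    mgrl[4:16, 4:16] = 1
    out, _ = L.gcdt(img, mgrl)
    assert np.all(mgrl[out > 0] == out[out > 0])  # P' subset of its class region
    with pytest.raises(ValueError, match="no foreground"):
        L.gcdt(img, np.zeros((20, 20), dtype=np.uint8))


# -- denoising ---------------------------------------------------------------

def median_oracle(mask, window):
    h, w = mask.shape
    r = window // 2
    out = np.zeros_like(mask)
    padded = np.pad(mask, r, mode="edge")
    for i in range(h):
        for j in range(w):
            out[i, j] = np.median(padded[i:i + window, j:j + window])
    return out


def test_denoise_isolated_pixel_and_block():
    m = np.zeros((7, 7), dtype=np.uint8)
    m[3, 3] = 1
    assert not L.denoise_mask(m, "median").any()
    block = np.zeros((14, 14), dtype=np.uint8)
    block[2:12, 2:12] = 1
    for kind in ("average", "median"):
        assert np.all(L.denoise_mask(block, kind)[3:11, 3:11] == 1)


@pytest.mark.parametrize("seed", range(4))
def test_median_filter_matches_sliding_window_oracle(seed):
    rng = np.random.default_rng(seed)
    m = rng.integers(0, 2, (10, 10)).astype(np.uint8)
    assert np.array_equal(L.denoise_mask(m, "median", 3), median_oracle(m, 3))


def test_checkerboard_median():
    m = np.indices((4, 4)).sum(axis=0) % 2
    assert np.array_equal(L.denoise_mask(m.astype(np.uint8), "median", 3), median_oracle(m, 3))


def test_denoise_even_window_rejected():
    with pytest.raises(ValueError, match="odd"):
        L.denoise_mask(np.zeros((4, 4), dtype=np.uint8), "median", 4)
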