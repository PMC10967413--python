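"""Segmentation: calibration, classification, refinement, density."""

import numpy as np
import pytest

from hairtube import (
    ColorCalibration,
    ColorRange,
    OverrideAnnotation,
    PixelClass,
    Region,
    apply_overrides,
    calibrate_from_patches,
    classify_pixels,
    compute_density,
    default_calibration,
    load_image,
    process_sheet,
    refine_mask,
)
from hairtube.synthetic import generate_sheet

from conftest import SMALL_TAPE, small_spec


# --- image IO ---------------------------------------------------------------


def test_round_trip_single_red_pixel(tmp_path):
    import imageio.v3 as iio

    px = np.full((1, 1, 3), (200, 30, 30), dtype=np.uint8)
    path = tmp_path / "red.png"
    iio.imwrite(path, px)
    loaded = load_image(path)
    assert loaded.shape == (1, 1, 3)
    assert tuple(loaded[0, 0]) == (200, 30, 30)


@pytest.mark.parametrize("fmt", ["png", "tiff"])
def test_round_trip_generated_sheet(tmp_path, small_sheet, fmt):
    import imageio.v3 as iio

    path = tmp_path / f"sheet.{fmt}"
    iio.imwrite(path, small_sheet.image)
    assert np.array_equal(load_image(path), small_sheet.image)


def test_load_image_missing_path(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_image(tmp_path / "nope.png")


def test_load_image_rejects_non_image(tmp_path):
    bad = tmp_path / "notes.tiff"
    bad.write_text("this is not an image")
    with pytest.raises(ValueError):
        load_image(bad)


# --- calibration ------------------------------------------------------------


def test_calibrate_uniform_patch():
    img = np.full((20, 20, 3), (200, 30, 30), dtype=np.uint8)
    cal = calibrate_from_patches(
        img, Region("bg", 0, 0, 10, 10), Region("tp", 10, 10, 20, 20), tolerance=10
    )
    assert cal.background.low == (190, 20, 20)
    assert cal.background.high == (210, 40, 40)


def test_calibrate_clips_at_channel_max():
    img = np.full((2, 2, 3), (250, 10, 10), dtype=np.uint8)
    img[0, 1] = (255, 20, 20)
    cal = calibrate_from_patches(
        img, Region("bg", 0, 1, 2, 2), Region("tp", 0, 0, 2, 1), tolerance=10
    )
    assert cal.tape.high == (255, 30, 30)
    assert cal.tape.low == (240, 0, 0)


def test_calibrate_noisy_patch_matches_exhaustive_scan(rng):
    img = rng.integers(0, 256, size=(30, 40, 3), dtype=np.uint8)
    patch = Region("bg", 5, 3, 25, 17)
    tol = 7
    cal = calibrate_from_patches(img, patch, Region("tp", 0, 0, 4, 2), tolerance=tol)
    # independent per-pixel min/max scan
    lo = [255, 255, 255]
    hi = [0, 0, 0]
    for y in range(patch.y0, patch.y1):
        for x in range(patch.x0, patch.x1):
            for c in range(3):
                lo[c] = min(lo[c], int(img[y, x, c]))
                hi[c] = max(hi[c], int(img[y, x, c]))
    assert cal.background.low == tuple(max(0, v - tol) for v in lo)
    assert cal.background.high == tuple(min(255, v + tol) for v in hi)


def test_calibrate_identical_ranges_warns():
    img = np.full((4, 4, 3), 120, dtype=np.uint8)
    with pytest.warns(UserWarning, match="identical"):
        calibrate_from_patches(
            img, Region("bg", 0, 0, 2, 2), Region("tp", 2, 2, 4, 4)
        )


def test_default_calibration_separates_nominal_colors():
    cal = default_calibration()
    spec = small_spec()
    assert cal.background.contains(spec.background_color)
    assert cal.tape.contains(spec.tape_color)
    assert not cal.background.contains(spec.hair_color)
    assert not cal.tape.contains(spec.hair_color)


# --- classification ---------------------------------------------------------


def _scalar_classify(pixel, cal):
    """Independent per-pixel oracle: explicit range checks, bg precedence."""
    if cal.background.contains(pixel):
        return PixelClass.BACKGROUND
    if cal.tape.contains(pixel):
        return PixelClass.TAPE
    return PixelClass.HAIR


def test_classify_trivial_pixels(calibration):
    mid_bg = np.array([[[200, 45, 45]]], dtype=np.uint8)  # bg range midpoint
    assert classify_pixels(mid_bg, calibration)[0, 0] == PixelClass.BACKGROUND
    near_black = np.array([[[5, 5, 5]]], dtype=np.uint8)
    assert classify_pixels(near_black, calibration)[0, 0] == PixelClass.HAIR


def test_classify_background_precedence_on_overlap():
    cal = ColorCalibration(
        background=ColorRange((0, 0, 0), (255, 255, 255)),
        tape=ColorRange((0, 0, 0), (255, 255, 255)),
    )
    img = np.full((2, 2, 3), 128, dtype=np.uint8)
    assert np.all(classify_pixels(img, cal) == PixelClass.BACKGROUND)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_classify_matches_per_pixel_oracle(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    lows = rng.integers(0, 200, size=(2, 3))
    highs = lows + rng.integers(10, 56, size=(2, 3))
    cal = ColorCalibration(
        background=ColorRange(tuple(lows[0]), tuple(np.minimum(highs[0], 255))),
        tape=ColorRange(tuple(lows[1]), tuple(np.minimum(highs[1], 255))),
    )
    mask = classify_pixels(img, cal)
    for y in range(16):
        for x in range(16):
            assert mask[y, x] == _scalar_classify(tuple(img[y, x]), cal)


# --- refinement -------------------------------------------------------------


def test_refine_identity_configuration(small_sheet, calibration):
    mask = classify_pixels(small_sheet.image, calibration)
    assert np.array_equal(refine_mask(mask, close_kernel=1, speck_area_min=0), mask)


def _naive_closing(bg: np.ndarray, k: int) -> np.ndarray:
    """Direct dilate-then-erode with a k x k square, loops only."""
    h, w = bg.shape
    r = k // 2
    dil = np.zeros_like(bg)
    for y in range(h):
        for x in range(w):
            window = bg[max(0, y - r) : y + r + 1, max(0, x - r) : x + r + 1]
            dil[y, x] = window.any()
    ero = np.zeros_like(bg)
    for y in range(h):
        for x in range(w):
            window = dil[max(0, y - r) : y + r + 1, max(0, x - r) : x + r + 1]
            ero[y, x] = window.all()
    return ero


def test_refine_closing_fills_isolated_tape_pixel():
    mask = np.full((9, 9), PixelClass.BACKGROUND, dtype=np.uint8)
    mask[4, 4] = PixelClass.TAPE
    out = refine_mask(mask, close_kernel=3, speck_area_min=0)
    assert out[4, 4] == PixelClass.BACKGROUND
    # closing may only add background pixels, and the addition matches
    # the direct dilate-erode computation in the interior
    bg = mask == PixelClass.BACKGROUND
    expected = bg | _naive_closing(bg, 3)
    assert np.array_equal(out == PixelClass.BACKGROUND, expected)


def _flood_components(hair: np.ndarray):
    """Exhaustive 8-connected flood fill, independent of scipy labelling."""
    h, w = hair.shape
    seen = np.zeros_like(hair, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if hair[y, x] and not seen[y, x]:
                stack = [(y, x)]
                seen[y, x] = True
                comp = []
                while stack:
                    cy, cx = stack.pop()
                    comp.append((cy, cx))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if 0 <= ny < h and 0 <= nx < w and hair[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(comp)
    return comps


def test_refine_speck_removal_matches_flood_fill_oracle(rng):
    mask = np.full((20, 20), PixelClass.TAPE, dtype=np.uint8)
    mask[3, 3] = mask[3, 4] = PixelClass.HAIR  # 2-px speck
    yy, xx = np.meshgrid(np.arange(10, 18), np.arange(5, 10), indexing="ij")
    mask[yy.ravel()[:40], xx.ravel()[:40]] = PixelClass.HAIR  # 40-px strand
    out = refine_mask(mask, close_kernel=1, speck_area_min=3)
    assert out[3, 3] == PixelClass.TAPE and out[3, 4] == PixelClass.TAPE
    assert np.count_nonzero(out == PixelClass.HAIR) == 40
    # full agreement with the flood-fill oracle
    expected = mask.copy()
    for comp in _flood_components(mask == PixelClass.HAIR):
        if len(comp) < 3:
            for y, x in comp:
                expected[y, x] = PixelClass.TAPE
    assert np.array_equal(out, expected)


def test_refine_rejects_even_kernel():
    mask = np.zeros((4, 4), dtype=np.uint8)
    with pytest.raises(ValueError):
        refine_mask(mask, close_kernel=2)


# --- overrides --------------------------------------------------------------


def test_overrides_empty_identity(small_sheet, calibration):
    mask = classify_pixels(small_sheet.image, calibration)
    assert np.array_equal(apply_overrides(mask, []), mask)


def test_override_relabels_exactly_region():
    mask = np.full((10, 10), PixelClass.HAIR, dtype=np.uint8)
    ov = OverrideAnnotation(Region("o", 2, 2, 7, 7), PixelClass.TAPE)
    out = apply_overrides(mask, [ov])
    assert np.count_nonzero(out == PixelClass.TAPE) == 25
    assert np.count_nonzero(out != mask) == 25


def test_overlapping_overrides_last_wins_and_idempotent():
    mask = np.full((10, 10), PixelClass.HAIR, dtype=np.uint8)
    first = OverrideAnnotation(Region("a", 0, 0, 6, 6), PixelClass.BACKGROUND)
    second = OverrideAnnotation(Region("b", 3, 3, 8, 8), PixelClass.TAPE)
    out = apply_overrides(mask, [first, second])
    assert np.all(out[3:6, 3:6] == PixelClass.TAPE)
    assert np.array_equal(apply_overrides(out, [second]), out)  # idempotence


def test_override_out_of_bounds_raises():
    mask = np.zeros((5, 5), dtype=np.uint8)
    ov = OverrideAnnotation(Region("o", 0, 0, 9, 9), PixelClass.TAPE)
    with pytest.raises(ValueError):
        apply_overrides(mask, [ov])


def test_override_may_not_target_hair():
    with pytest.raises(ValueError):
        OverrideAnnotation(Region("o", 0, 0, 1, 1), PixelClass.HAIR)


# --- density ----------------------------------------------------------------


def test_density_all_tape_is_zero():
    mask = np.full((100, 100), PixelClass.TAPE, dtype=np.uint8)
    res = compute_density(mask, Region("r", 0, 0, 100, 100))
    assert res.density_percent == 0.0 and res.defined


def test_density_all_hair_is_hundred():
    mask = np.full((10, 10), PixelClass.HAIR, dtype=np.uint8)
    mask[0, 0] = PixelClass.BACKGROUND
    res = compute_density(mask, Region("r", 0, 0, 10, 10))
    assert res.density_percent == 100.0


def test_density_ratio_definition():
    mask = np.full((100, 100), PixelClass.TAPE, dtype=np.uint8)
    mask.ravel()[:250] = PixelClass.HAIR
    res = compute_density(mask, Region("r", 0, 0, 100, 100))
    assert res.n_hair == 250 and res.n_tape == 9750
    assert res.density_percent == pytest.approx(2.5)


def test_density_undefined_is_flagged_not_zero():
    mask = np.full((5, 5), PixelClass.BACKGROUND, dtype=np.uint8)
    res = compute_density(mask, Region("r", 0, 0, 5, 5))
    assert not res.defined
    assert np.isnan(res.density_percent)


# --- whole-sheet pipeline ---------------------------------------------------


def test_process_sheet_zero_density(calibration):
    sheet = generate_sheet(small_spec(target_density=0.0, seed=3))
    results = process_sheet(sheet.image, calibration, [SMALL_TAPE])
    assert results[0].density_percent == 0.0


def test_process_sheet_equals_stepwise_composition(small_sheet, calibration):
    ov = OverrideAnnotation(Region("o", 60, 50, 70, 60), PixelClass.TAPE)
    whole = process_sheet(small_sheet.image, calibration, [SMALL_TAPE], [ov])
    mask = classify_pixels(small_sheet.image, calibration)
    mask = refine_mask(mask, close_kernel=3, speck_area_min=3)
    mask = apply_overrides(mask, [ov])
    step = compute_density(mask, SMALL_TAPE)
    assert whole[0] == step


def test_disjoint_regions_are_independent(small_sheet, calibration):
    left = Region("left", 50, 40, 150, 160)
    right = Region("right", 150, 40, 250, 160)
    both = process_sheet(small_sheet.image, calibration, [left, right])
    alone = [
        process_sheet(small_sheet.image, calibration, [r])[0] for r in (left, right)
    ]
    assert both == alone
    assert [r.label for r in both] == ["left", "right"]


def test_partition_conserved_at_every_stage(small_sheet, calibration):
    region = SMALL_TAPE
    mask = classify_pixels(small_sheet.image, calibration)
    for stage in (
        mask,
        refine_mask(mask),
        apply_overrides(
            refine_mask(mask),
            [OverrideAnnotation(Region("o", 55, 45, 65, 55), PixelClass.BACKGROUND)],
        ),
    ):
        res = compute_density(stage, region)
        assert res.n_background + res.n_tape + res.n_hair == region.area


def test_translation_invariance(small_sheet, calibration):
    img = small_sheet.image
    h, w = img.shape[:2]
    dx, dy = 17, 9
    bg = np.array(small_sheet.spec.background_color, dtype=np.uint8)
    canvas0 = np.broadcast_to(bg, (h + 30, w + 30, 3)).copy()
    canvas1 = canvas0.copy()
    canvas0[:h, :w] = img
    canvas1[dy : dy + h, dx : dx + w] = img
    res0 = process_sheet(canvas0, calibration, [SMALL_TAPE])
    res1 = process_sheet(canvas1, calibration, [SMALL_TAPE.shifted(dx, dy)])
    r0, r1 = res0[0], res1[0]
    assert (r0.n_background, r0.n_tape, r0.n_hair) == (
        r1.n_background,
        r1.n_tape,
        r1.n_hair,
    )


def test_painting_extra_strand_never_decreases_density(calibration):
    sheet = generate_sheet(small_spec(seed=8))
    base = process_sheet(sheet.image, calibration, [SMALL_TAPE])[0]
    img = sheet.image.copy()
    # a fresh hair patch disjoint from existing hair in the truth mask
    ys, xs = np.where(sheet.truth[SMALL_TAPE.slices] == PixelClass.TAPE)
    y, x = ys[0] + SMALL_TAPE.y0, xs[0] + SMALL_TAPE.x0
    block = (slice(y, min(y + 4, SMALL_TAPE.y1)), slice(x, min(x + 12, SMALL_TAPE.x1)))
    img[block] = sheet.spec.hair_color
    more = process_sheet(img, calibration, [SMALL_TAPE])[0]
    assert more.density_percent >= base.density_percent


def test_density_bounds_across_targets(calibration):
    for target in (0.5, 5.0, 40.0):
        sheet = generate_sheet(small_spec(target_density=target, seed=int(target)))
        res = process_sheet(sheet.image, calibration, [SMALL_TAPE])[0]
        assert 0.0 <= res.density_percent <= 100.0
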