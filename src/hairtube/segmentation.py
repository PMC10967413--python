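"""Pixel classification and hair-density computation for scanned tape sheets.

Hair tubes collect dorsal guard hair of small mammals on double-sided
adhesive tape. The tapes are mounted on a saturated red background and
scanned (8-bit RGB, nominally 600 dpi). Every pixel of the scan is
assigned to exactly one of three classes — *background*, *tape*, or
*hair* — by inclusive per-channel RGB range tests. The two ranges are
calibrated from user-designated patches containing only background or
only tape, or taken from package defaults. Anything that matches
neither range is hair (the residual class). Hair density inside a
rectangular region of interest is then

    density (%) = 100 * n_hair / (n_hair + n_tape)

i.e. the share of hair among the *effective* pixels; background pixels
are excluded from the denominator because the hair lies on the tape.

Classification happens in RGB colour space; a second pass in pixel
space (morphological closing of the background, removal of tiny hair
specks) absorbs deviations caused by brightness variance, dust, and
tape surface roughness.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _morph_closing


class PixelClass(enum.IntEnum):
    """Exhaustive pixel partition of a scanned sheet."""

    BACKGROUND = 0
    TAPE = 1
    HAIR = 2


_RGB = tuple[int, int, int]


@dataclass(frozen=True)
class ColorRange:
    """Inclusive per-channel RGB box, ``low[c] <= value[c] <= high[c]``."""

    low: _RGB
    high: _RGB

    def __post_init__(self) -> None:
        for lo, hi in zip(self.low, self.high):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(
                    f"invalid colour range: low={self.low} high={self.high}"
                )

    def contains(self, pixel: Sequence[int]) -> bool:
        return all(lo <= v <= hi for lo, v, hi in zip(self.low, pixel, self.high))

    def mask(self, image: np.ndarray) -> np.ndarray:
        """Boolean membership mask for an (H, W, 3) image."""
        low = np.asarray(self.low, dtype=np.int16)
        high = np.asarray(self.high, dtype=np.int16)
        img = image.astype(np.int16, copy=False)
        return np.all((img >= low) & (img <= high), axis=-1)


@dataclass(frozen=True)
class ColorCalibration:
    """Background and tape ranges plus the per-channel patch tolerance.

    The ranges may overlap; an overlapping pixel is labelled background
    (the red background gives the largest colour separation, and a
    background-over-tape mistake is visible and correctable with an
    override, whereas silently losing hair is not).
    """

    background: ColorRange
    tape: ColorRange
    tolerance: int = 10

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


#: Package defaults, tuned to the nominal synthetic colours
#: (background (200,30,30), tape (230,205,170), hair (40,30,25)) and
#: configurable through ``ColorCalibration`` / the run config.
DEFAULT_BACKGROUND_RANGE = ColorRange((150, 0, 0), (255, 90, 90))
DEFAULT_TAPE_RANGE = ColorRange((180, 150, 110), (255, 235, 210))
DEFAULT_TOLERANCE = 10


def default_calibration() -> ColorCalibration:
    """Default RGB calibration: saturated-red background, pale neutral tape."""
    return ColorCalibration(
        background=DEFAULT_BACKGROUND_RANGE,
        tape=DEFAULT_TAPE_RANGE,
        tolerance=DEFAULT_TOLERANCE,
    )


@dataclass(frozen=True)
class Region:
    """Half-open axis-aligned rectangle ``[x0, x1) x [y0, y1)``, 0-based.

    x runs rightward, y downward (matrix row order).
    """

    label: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(f"degenerate region {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def shifted(self, dx: int, dy: int) -> "Region":
        return Region(self.label, self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)


@dataclass(frozen=True)
class OverrideAnnotation:
    """Manual reassignment of a rectangle to background or tape.

    Interfering elements (dirt, plant particles, ragged tape edges) are
    assigned to background or tape; hair is never an override target.
    """

    region: Region
    target_class: PixelClass

    def __post_init__(self) -> None:
        if self.target_class == PixelClass.HAIR:
            raise ValueError("overrides may only target background or tape")


@dataclass(frozen=True)
class DensityResult:
    """Per-region class counts and hair density.

    ``defined`` is False when the region holds no effective (hair or
    tape) pixels; ``density_percent`` is then NaN, never silently 0.
    """

    label: str
    n_background: int
    n_tape: int
    n_hair: int
    density_percent: float
    defined: bool

    @classmethod
    def from_counts(
        cls, label: str, n_background: int, n_tape: int, n_hair: int
    ) -> "DensityResult":
        effective = n_tape + n_hair
        if effective == 0:
            return cls(label, n_background, n_tape, n_hair, float("nan"), False)
        return cls(
            label, n_background, n_tape, n_hair, 100.0 * n_hair / effective, True
        )


def load_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG sheet as an (H, W, 3) uint8 RGB array.

    Channels are returned in (R, G, B) order regardless of on-disk byte
    order; an alpha channel, if present, is dropped.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image not found: {p}")
    try:
        arr = iio.imread(p)
    except Exception as exc:  # imageio raises plugin-specific types
        raise ValueError(f"unreadable or unsupported image: {p}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ValueError(
            f"expected an 8-bit RGB image, got shape {arr.shape} for {p}"
        )
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit channels, got {arr.dtype} for {p}")
    return np.ascontiguousarray(arr[..., :3])


def _check_region(region: Region, shape: tuple[int, ...]) -> None:
    height, width = shape[:2]
    if region.x1 > width or region.y1 > height:
        raise ValueError(
            f"region {region.label!r} [{region.x0},{region.x1})x[{region.y0},{region.y1}) "
            f"exceeds image bounds {width}x{height}"
        )


def calibrate_from_patches(
    image: np.ndarray,
    bg_patch: Region,
    tape_patch: Region,
    tolerance: int = DEFAULT_TOLERANCE,
) -> ColorCalibration:
    """Derive RGB ranges from single-class calibration patches.

    Per class and channel: ``low = max(0, patch min - tolerance)`` and
    ``high = min(255, patch max + tolerance)``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")

    def patch_range(patch: Region) -> ColorRange:
        _check_region(patch, image.shape)
        pixels = image[patch.slices].reshape(-1, 3)
        if pixels.size == 0:
            raise ValueError(f"empty calibration patch {patch.label!r}")
        lo = np.maximum(pixels.min(axis=0).astype(int) - tolerance, 0)
        hi = np.minimum(pixels.max(axis=0).astype(int) + tolerance, 255)
        return ColorRange(tuple(lo.tolist()), tuple(hi.tolist()))

    background = patch_range(bg_patch)
    tape = patch_range(tape_patch)
    if background == tape:
        warnings.warn(
            "background and tape calibration ranges are identical; "
            "classification cannot separate the two classes",
            stacklevel=2,
        )
    return ColorCalibration(background=background, tape=tape, tolerance=tolerance)


def classify_pixels(image: np.ndarray, calibration: ColorCalibration) -> np.ndarray:
    """Label every pixel background, tape, or hair (residual class).

    The background test takes precedence where the two calibration
    ranges overlap.
    """
    mask = np.full(image.shape[:2], PixelClass.HAIR, dtype=np.uint8)
    mask[calibration.tape.mask(image)] = PixelClass.TAPE
    mask[calibration.background.mask(image)] = PixelClass.BACKGROUND
    return mask


def refine_mask(
    mask: np.ndarray, close_kernel: int = 3, speck_area_min: int = 3
) -> np.ndarray:
    """Pixel-space cleanup of a classified mask.

    1. Morphological closing (square element of side ``close_kernel``)
       of the background class, filling pinholes left by dust or noise.
       Closing the tape class instead would erase genuine 1-px hairs.
    2. 8-connected hair components with area < ``speck_area_min`` are
       reassigned to tape (dust on tape, noise tails).

    The three-class partition is preserved.
    """
    if close_kernel < 1 or close_kernel % 2 == 0:
        raise ValueError("close_kernel must be odd and >= 1")
    if speck_area_min < 0:
        raise ValueError("speck_area_min must be >= 0")
    out = mask.copy()
    if close_kernel > 1:
        bg = out == PixelClass.BACKGROUND
        closed = _morph_closing(bg, footprint=np.ones((close_kernel, close_kernel), bool))
        out[closed & ~bg] = PixelClass.BACKGROUND
    if speck_area_min > 0:
        hair = out == PixelClass.HAIR
        labels, n = ndimage.label(hair, structure=np.ones((3, 3), dtype=int))
        if n:
            areas = np.bincount(labels.ravel())
            small = areas < speck_area_min
            small[0] = False
            out[small[labels]] = PixelClass.TAPE
    return out


def apply_overrides(
    mask: np.ndarray, overrides: Iterable[OverrideAnnotation]
) -> np.ndarray:
    """Apply manual class reassignments; later overrides win on overlap."""
    out = mask.copy()
    for override in overrides:
        _check_region(override.region, out.shape)
        out[override.region.slices] = override.target_class
    return out


def compute_density(mask: np.ndarray, region: Region) -> DensityResult:
    """Count classes inside a region and form the hair-density ratio."""
    _check_region(region, mask.shape)
    counts = np.bincount(mask[region.slices].ravel(), minlength=3)
    return DensityResult.from_counts(
        region.label, int(counts[0]), int(counts[1]), int(counts[2])
    )


def process_sheet(
    image: np.ndarray,
    calibration: ColorCalibration,
    regions: Sequence[Region],
    overrides: Sequence[OverrideAnnotation] = (),
    close_kernel: int = 3,
    speck_area_min: int = 3,
) -> list[DensityResult]:
    """Full per-sheet pipeline: classify, refine, override, per-region density.

    Results are returned in input region order, each identical to
    running the component operations in sequence.
    """
    if not regions:
        raise ValueError("at least one region is required")
    mask = classify_pixels(image, calibration)
    mask = refine_mask(mask, close_kernel=close_kernel, speck_area_min=speck_area_min)
    mask = apply_overrides(mask, overrides)
    return [compute_density(mask, region) for region in regions]
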