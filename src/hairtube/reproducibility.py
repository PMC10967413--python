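"""Reproducibility protocol: jittered region re-selection and error summaries.

The calculated hair density of a tape section is defined as the mean
over repeated runs (default 10) in which the region of interest is
re-drawn with small random offsets of its four edges, emulating the
variability of realistic manual region selection. The spread of the
replicates gives the standard error of the calculated value. Against
a pixel-exact ground-truth mask, the "real" density is computed with
the same ratio definition, and real-vs-calculated pairs are summarised
by the mean absolute error and the R² of an ordinary least-squares fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .segmentation import (
    ColorCalibration,
    OverrideAnnotation,
    Region,
    apply_overrides,
    classify_pixels,
    compute_density,
    refine_mask,
)


@dataclass(frozen=True)
class PerturbationSpec:
    """Edge-jitter settings for region re-selection.

    jitter: maximum absolute per-edge offset in pixels (default 3 px,
    a realistic hand-placement wobble at 600 dpi).
    """

    jitter: int = 3
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass(frozen=True)
class ReproSummary:
    """Replicate densities with mean, sample SD (ddof=1) and SE = SD/sqrt(n)."""

    replicate_densities: tuple[float, ...]
    mean: float
    sd: float
    se: float
    n_excluded: int = 0


@dataclass(frozen=True)
class ErrorSummary:
    """Real-vs-calculated agreement over a set of regions/sheets.

    r_squared is the coefficient of determination of the OLS fit of
    calculated on real density; None when fewer than 3 pairs are given.
    """

    pairs: tuple[tuple[float, float], ...]
    mean_abs_error: float
    r_squared: float | None


_MAX_JITTER_RETRIES = 100


def jitter_region(
    region: Region,
    spec: PerturbationSpec,
    draw_index: int,
    image_shape: tuple[int, int],
) -> Region:
    """Offset each region edge by an independent uniform integer in [-j, j].

    Deterministic in ``(spec.seed, draw_index)``. The result is clipped
    to the image bounds; a degenerate (empty) draw is re-drawn up to a
    bounded number of times.
    """
    height, width = image_shape[:2]
    if spec.jitter == 0:
        return region
    rng = np.random.default_rng([spec.seed, draw_index])
    j = spec.jitter
    for _ in range(_MAX_JITTER_RETRIES):
        dx0, dy0, dx1, dy1 = rng.integers(-j, j + 1, size=4)
        x0 = int(np.clip(region.x0 + dx0, 0, width))
        y0 = int(np.clip(region.y0 + dy0, 0, height))
        x1 = int(np.clip(region.x1 + dx1, 0, width))
        y1 = int(np.clip(region.y1 + dy1, 0, height))
        if x0 < x1 and y0 < y1:
            return Region(region.label, x0, y0, x1, y1)
    raise ValueError(
        f"could not draw a non-empty jittered region for {region.label!r} "
        f"(jitter={spec.jitter})"
    )


def replicate_density(
    image: np.ndarray,
    calibration: ColorCalibration,
    region: Region,
    spec: PerturbationSpec,
    overrides: Sequence[OverrideAnnotation] = (),
    close_kernel: int = 3,
    speck_area_min: int = 3,
) -> ReproSummary:
    """Calculated density: mean over jittered-region replicates.

    The classified and refined mask does not depend on the region, so
    it is computed once and re-counted per replicate — arithmetically
    identical to running the full pipeline for every replicate.
    Replicates with undefined density (no effective pixels) are
    excluded with a warning; an all-undefined run is an error.
    """
    mask = classify_pixels(image, calibration)
    mask = refine_mask(mask, close_kernel=close_kernel, speck_area_min=speck_area_min)
    mask = apply_overrides(mask, overrides)

    densities: list[float] = []
    excluded = 0
    for i in range(spec.repetitions):
        jittered = jitter_region(region, spec, i, image.shape[:2])
        result = compute_density(mask, jittered)
        if result.defined:
            densities.append(result.density_percent)
        else:
            excluded += 1
            warnings.warn(
                f"replicate {i} of region {region.label!r} has no effective "
                "pixels; excluded from the summary",
                stacklevel=2,
            )
    if not densities:
        raise ValueError(
            f"all {spec.repetitions} replicates of region {region.label!r} "
            "had undefined density"
        )
    return summarize_replicates(densities, n_excluded=excluded)


def summarize_replicates(
    densities: Sequence[float], n_excluded: int = 0
) -> ReproSummary:
    """Mean, sample SD (ddof=1) and SE = SD/sqrt(n) of replicate densities."""
    arr = np.asarray(densities, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate densities to summarize")
    mean = float(arr.mean())
    if arr.size == 1 or np.ptp(arr) == 0.0:
        sd = 0.0  # exactly zero for identical replicates
    else:
        sd = float(arr.std(ddof=1))
    se = sd / math.sqrt(arr.size)
    return ReproSummary(tuple(arr.tolist()), mean, sd, se, n_excluded=n_excluded)


def true_density(truth_mask: np.ndarray, region: Region) -> float:
    """Ground-truth density from a pixel-exact class mask, same ratio rule."""
    result = compute_density(truth_mask, region)
    if not result.defined:
        raise ValueError(
            f"region {region.label!r} holds no effective pixels in the truth mask"
        )
    return result.density_percent


def error_summary(pairs: Sequence[tuple[float, float]]) -> ErrorSummary:
    """Summarise (real, calculated) density pairs.

    mean_abs_error in percentage points; r_squared from OLS of
    calculated on real (flagged None below 3 pairs).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("pairs must be a non-empty sequence of (real, calculated)")
    if not np.isfinite(arr).all():
        raise ValueError("pairs must be finite")
    mae = float(np.abs(arr[:, 1] - arr[:, 0]).mean())
    r_squared: float | None = None
    if arr.shape[0] >= 3 and np.ptp(arr[:, 0]) > 0 and np.ptp(arr[:, 1]) > 0:
        fit = stats.linregress(arr[:, 0], arr[:, 1])
        r_squared = float(fit.rvalue**2)
    return ErrorSummary(tuple(map(tuple, arr.tolist())), mae, r_squared)
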