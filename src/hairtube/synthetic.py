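"""Synthetic scanned sheets with pixel-exact truth, and synthetic field surveys.

Two generators make the whole package testable without any scanner or
field data:

* ``generate_sheet`` paints a red-background sheet with pale tape
  rectangles, a horizontal brightness gradient, per-pixel Gaussian
  colour noise, small dust specks, and dark curved hair strands
  (bounded-turning random walks). Every painted pixel's class is
  recorded in a ground-truth mask, so true per-region densities are
  exact by construction.

* ``generate_survey`` draws a latent small-mammal activity per
  (habitat, replicate, repetition) unit and couples it to both tape
  hair densities (saturating increasing function plus truncated noise)
  and camera-trap event streams (Poisson counts with rate proportional
  to activity), reproducing the field design of 3 habitats x 10
  replicates x 10 tubes x 2 tape sides x 4 repetitions = 2400 tapes
  and 40 aggregated datapoints per habitat.

Both generators are fully deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import PixelClass, Region, compute_density

_RGB = tuple[int, int, int]


@dataclass(frozen=True)
class TapeSpec:
    """Synthetic sheet description; defaults model one tape-section crop.

    Colours are nominal 8-bit RGB before gradient and noise. Strand
    geometry (step 3 px, turn <= 0.35 rad, 30-120 steps, widths 1-3 px)
    gives smooth curves of roughly 4-15 mm at 600 dpi, the scale of
    rodent guard hairs. ``target_density`` is the percentage of the
    tape area to cover with hair; strands are added until the realized
    truth density first reaches it (overshoot bounded by one strand).
    """

    width: int = 900
    height: int = 560
    background_color: _RGB = (200, 30, 30)
    tape_regions: tuple[Region, ...] = (Region("tape", 100, 80, 800, 480),)
    tape_color: _RGB = (230, 205, 170)
    hair_color: _RGB = (40, 30, 25)
    noise_sd: float = 4.0
    gradient_amplitude: float = 8.0
    dust_count: int = 25
    dust_size_range: tuple[int, int] = (1, 2)
    dust_color: _RGB = (110, 95, 80)
    strand_widths: tuple[int, ...] = (1, 2, 3)
    strand_width_probs: tuple[float, ...] = (0.3, 0.5, 0.2)
    strand_step: float = 3.0
    strand_max_turn: float = 0.35
    strand_steps_range: tuple[int, int] = (30, 120)
    target_density: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("sheet dimensions must be positive")
        if not 0.0 <= self.target_density <= 100.0:
            raise ValueError("target_density must lie in [0, 100]")
        if len(self.strand_widths) != len(self.strand_width_probs):
            raise ValueError("strand width/probability lengths differ")
        for region in self.tape_regions:
            if region.x1 > self.width or region.y1 > self.height:
                raise ValueError(f"tape region {region.label!r} exceeds the sheet")
        self._check_separation()

    def _check_separation(self) -> None:
        # nominal colours must be separable despite noise + calibration slack
        margin = 2.0 * (self.noise_sd + 10.0)
        for name_a, a, name_b, b in (
            ("background", self.background_color, "tape", self.tape_color),
            ("background", self.background_color, "hair", self.hair_color),
            ("tape", self.tape_color, "hair", self.hair_color),
        ):
            if max(abs(x - y) for x, y in zip(a, b)) <= margin:
                raise ValueError(
                    f"nominal {name_a}/{name_b} colours are not separable "
                    f"(need > {margin:.0f} in at least one channel)"
                )


@dataclass(frozen=True)
class SyntheticSheet:
    """Generated image plus its exact truth mask and per-region truth densities."""

    image: np.ndarray
    truth: np.ndarray
    region_densities: dict[str, float]
    spec: TapeSpec


def _stamp_offsets(width: int) -> np.ndarray:
    """Integer disk footprint offsets for a strand of the given width."""
    if width <= 1:
        return np.zeros((1, 2), dtype=int)
    r = width / 2.0
    span = np.arange(-width, width + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    keep = dy**2 + dx**2 <= r**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _paint_strand(
    truth: np.ndarray,
    region: Region,
    rng: np.random.Generator,
    spec: TapeSpec,
) -> int:
    """Random-walk one strand inside a tape region; returns new hair pixels.

    The polyline is densified to sub-pixel spacing before stamping so a
    strand is a connected curve at every width (a real hair never
    appears as a dotted line of isolated pixels).
    """
    width = int(rng.choice(spec.strand_widths, p=spec.strand_width_probs))
    offsets = _stamp_offsets(width)
    n_steps = int(rng.integers(spec.strand_steps_range[0], spec.strand_steps_range[1] + 1))
    start = np.array(
        [rng.uniform(region.y0, region.y1), rng.uniform(region.x0, region.x1)]
    )
    heading = rng.uniform(0.0, 2.0 * math.pi)
    turns = rng.uniform(-spec.strand_max_turn, spec.strand_max_turn, size=n_steps)
    headings = heading + np.concatenate([[0.0], np.cumsum(turns)])
    steps = spec.strand_step * np.stack(
        [np.sin(headings), np.cos(headings)], axis=1
    )  # (dy, dx)
    points = start + np.concatenate(
        [np.zeros((1, 2)), np.cumsum(steps, axis=0)], axis=0
    )

    # densify segments to <= ~0.7 px spacing, then stamp the footprint
    k = max(1, int(math.ceil(spec.strand_step / 0.7)))
    t = np.linspace(0.0, 1.0, k, endpoint=False)
    seg = points[1:] - points[:-1]
    dense = (points[:-1, None, :] + seg[:, None, :] * t[None, :, None]).reshape(-1, 2)
    dense = np.concatenate([dense, points[-1:, :]], axis=0)
    centers = np.rint(dense).astype(int)

    cy = (centers[:, 0, None] + offsets[None, :, 0]).ravel()
    cx = (centers[:, 1, None] + offsets[None, :, 1]).ravel()
    keep = (
        (cx >= region.x0) & (cx < region.x1) & (cy >= region.y0) & (cy < region.y1)
    )
    cy, cx = cy[keep], cx[keep]
    if cy.size == 0:
        return 0
    flat = np.unique(cy.astype(np.int64) * truth.shape[1] + cx)
    fresh = truth.ravel()[flat] == PixelClass.TAPE
    truth.ravel()[flat] = PixelClass.HAIR
    return int(fresh.sum())


_MAX_STRANDS = 100_000


def generate_sheet(spec: TapeSpec) -> SyntheticSheet:
    """Render a synthetic scanned sheet and its pixel-exact truth mask."""
    rng = np.random.default_rng(spec.seed)

    truth = np.full((spec.height, spec.width), PixelClass.BACKGROUND, dtype=np.uint8)
    for region in spec.tape_regions:
        truth[region.slices] = PixelClass.TAPE

    tape_area = int(np.count_nonzero(truth == PixelClass.TAPE))
    if spec.target_density > 0 and tape_area == 0:
        raise ValueError("target density > 0 requires a non-empty tape area")

    # hair strands: add until the realized density first reaches the target
    n_hair = 0
    if spec.target_density > 0:
        areas = np.array([r.area for r in spec.tape_regions], dtype=float)
        target_px = spec.target_density / 100.0 * tape_area
        for _ in range(_MAX_STRANDS):
            if n_hair >= target_px:
                break
            region = spec.tape_regions[rng.choice(len(areas), p=areas / areas.sum())]
            n_hair += _paint_strand(truth, region, rng, spec)
        else:
            raise ValueError("target density unreachable (strand painting stalled)")

    palette = np.array(
        [spec.background_color, spec.tape_color, spec.hair_color], dtype=float
    )
    image = palette[truth]

    # dust specks keep the underlying truth class (dirt is marked to
    # background/tape in manual ground truth, never to hair)
    lo, hi = spec.dust_size_range
    for _ in range(spec.dust_count):
        size = int(rng.integers(lo, hi + 1))
        y = int(rng.integers(0, spec.height))
        x = int(rng.integers(0, spec.width))
        ys = slice(y, min(y + 1, spec.height))
        xs = slice(x, min(x + size, spec.width))
        image[ys, xs] = spec.dust_color

    if spec.gradient_amplitude:
        ramp = np.linspace(-1.0, 1.0, spec.width) * spec.gradient_amplitude
        image += ramp[None, :, None]
    if spec.noise_sd:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    densities = {
        region.label: compute_density(truth, region).density_percent
        for region in spec.tape_regions
    }
    return SyntheticSheet(image=image, truth=truth, region_densities=densities, spec=spec)


# ---------------------------------------------------------------------------
# field-survey generator


#: Sighting mix matching the reported field totals (1220 Apodemus, 193
#: voles, 22 rats, 2 shrews).
DEFAULT_TAXON_PROBS: tuple[tuple[str, float], ...] = (
    ("Apodemus", 0.849),
    ("vole", 0.134),
    ("rat", 0.015),
    ("shrew", 0.002),
)


@dataclass(frozen=True)
class SurveySpec:
    """Field-survey design and latent-activity coupling parameters.

    The default design mirrors the validation study: per habitat, 10
    transect replicates of 10 tubes (2 tape sides each), repeated 4
    times, each repetition observed for a 3-day window. A latent
    activity ``a`` is drawn log-normally per (habitat, replicate,
    repetition); expected tape density follows the saturating curve
    ``density_max * a / (a + density_halfsat)`` and camera events are
    Poisson with rate ``camera_rate_per_activity * a`` per window.
    """

    habitats: tuple[str, ...] = ("grassland", "hedge", "wheat")
    replicates: int = 10
    tubes: int = 10
    sides: int = 2
    repetitions: int = 4
    activity_meanlog: Mapping[str, float] | None = None
    activity_sdlog: float = 0.7
    density_max: float = 25.0
    density_halfsat: float = 5.0
    density_noise_sd: float = 1.0
    tube_visit_rate: float = 0.25  # expected visits per tube per unit activity;
    # an unvisited tube stays hairless, so roughly half the tapes carry no
    # hair at default activity levels (math.inf disables the thinning)
    camera_rate_per_activity: float = 6.0
    camera_noise: bool = True  # False: deterministic rounded expected count
    window_s: float = 259_200.0  # 3 consecutive 24 h periods
    taxon_probs: tuple[tuple[str, float], ...] = DEFAULT_TAXON_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("replicates", self.replicates),
            ("tubes", self.tubes),
            ("sides", self.sides),
            ("repetitions", self.repetitions),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.density_max <= 0 or self.density_halfsat <= 0:
            raise ValueError("coupling must be strictly increasing")
        if abs(sum(p for _, p in self.taxon_probs) - 1.0) > 1e-9:
            raise ValueError("taxon probabilities must sum to 1")

    def meanlog(self, habitat: str) -> float:
        defaults = {"grassland": 0.9, "hedge": 1.4, "wheat": 0.9}
        table = dict(defaults, **(self.activity_meanlog or {}))
        return table.get(habitat, 1.0)

    def coupling(self, activity: float) -> float:
        """Expected tape density (percent) at a latent activity level."""
        return self.density_max * activity / (activity + self.density_halfsat)


@dataclass(frozen=True)
class SurveyDataset:
    """Tape records and camera events as tidy DataFrames."""

    tapes: pd.DataFrame
    events: pd.DataFrame
    spec: SurveySpec


def _unit_rng(seed: int, stream: int, unit: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, unit])


def _unit_records(
    spec: SurveySpec, habitat: str, replicate: int, repetition: int, unit: int,
    activity: float,
) -> tuple[list[dict], list[dict]]:
    """Tape and event rows for one (habitat, replicate, repetition) unit.

    All randomness is seeded per unit, and the camera count uses the
    inverse CDF on a common uniform, so that raising the activity of a
    unit (everything else fixed) never lowers its densities or count.
    """
    mean_density = spec.coupling(activity)
    rng_tape = _unit_rng(spec.seed, 1, unit)
    p_visit = 1.0 - math.exp(-spec.tube_visit_rate * activity)
    tapes = []
    for tube in range(1, spec.tubes + 1):
        # u and noise are drawn unconditionally so that raising the
        # activity under the same seed never lowers any density
        visited = rng_tape.uniform() < p_visit
        for side_idx in range(spec.sides):
            noise = rng_tape.normal(0.0, spec.density_noise_sd)
            density = (
                float(np.clip(mean_density + noise, 0.0, 100.0)) if visited else 0.0
            )
            tapes.append(
                {
                    "habitat": habitat,
                    "replicate": replicate,
                    "repetition": repetition,
                    "tube": tube,
                    "side": chr(ord("a") + side_idx),
                    "density_percent": density,
                }
            )

    mu = spec.camera_rate_per_activity * activity
    if spec.camera_noise:
        # inverse CDF on a per-unit common uniform: raising the activity
        # of a unit (same seed) can never lower its count
        rng_cam = _unit_rng(spec.seed, 2, unit)
        n_events = int(stats.poisson.ppf(rng_cam.uniform(), mu))
    else:
        n_events = int(round(mu))
    events = []
    if n_events:
        rng_stream = _unit_rng(spec.seed, 3, unit)
        times = np.sort(rng_stream.uniform(0.0, spec.window_s, size=n_events))
        taxa = rng_stream.choice(
            [t for t, _ in spec.taxon_probs],
            size=n_events,
            p=[p for _, p in spec.taxon_probs],
        )
        for t, taxon in zip(times, taxa):
            events.append(
                {
                    "habitat": habitat,
                    "replicate": replicate,
                    "repetition": repetition,
                    "timestamp_s": float(t),
                    "taxon": str(taxon),
                }
            )
    return tapes, events


def generate_survey(spec: SurveySpec) -> SurveyDataset:
    """Draw a full synthetic survey dataset, deterministic under the seed."""
    tape_rows: list[dict] = []
    event_rows: list[dict] = []
    unit = 0
    rng_activity = np.random.default_rng([spec.seed, 0])
    for habitat in spec.habitats:
        for replicate in range(1, spec.replicates + 1):
            for repetition in range(1, spec.repetitions + 1):
                activity = float(
                    rng_activity.lognormal(spec.meanlog(habitat), spec.activity_sdlog)
                )
                tapes, events = _unit_records(
                    spec, habitat, replicate, repetition, unit, activity
                )
                tape_rows.extend(tapes)
                event_rows.extend(events)
                unit += 1
    tapes_df = pd.DataFrame(tape_rows)
    events_df = pd.DataFrame(
        event_rows,
        columns=["habitat", "replicate", "repetition", "timestamp_s", "taxon"],
    )
    return SurveyDataset(tapes=tapes_df, events=events_df, spec=spec)
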