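"""YAML run-configuration parsing for scriptable, headless runs.

The original workflow was interactive (patch picking, region drawing,
override clicking); here every input lives in a structured config file
so runs are reproducible. Schema (all coordinates 0-based, half-open
rectangles, x rightward, y downward):

    seed: 1                       # optional, recorded in outputs
    calibration:
      mode: defaults              # or "ranges" or "patches"
      # mode: ranges
      #   background: {low: [150, 0, 0], high: [255, 90, 90]}
      #   tape:       {low: [180, 150, 110], high: [255, 235, 210]}
      # mode: patches             # single-class areas on the input image
      #   background_patch: {x0: 0, y0: 0, x1: 40, y1: 40}
      #   tape_patch:       {x0: 120, y0: 100, x1: 160, y1: 140}
      #   tolerance: 10
    regions:
      - {label: tape1, x0: 100, y0: 80, x1: 800, y1: 480}
    overrides:                    # optional; later entries win
      - {x0: 10, y0: 10, x1: 20, y1: 20, class: tape}
    refine:                       # optional
      close_kernel: 3
      speck_area_min: 3
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .segmentation import (
    ColorCalibration,
    ColorRange,
    OverrideAnnotation,
    PixelClass,
    Region,
    calibrate_from_patches,
    default_calibration,
)


@dataclass(frozen=True)
class RunConfig:
    """Parsed, validated run configuration."""

    calibration: ColorCalibration
    regions: tuple[Region, ...]
    overrides: tuple[OverrideAnnotation, ...]
    close_kernel: int = 3
    speck_area_min: int = 3
    seed: int = 0
    config_hash: str = ""


def _rect(entry: dict, label: str = "") -> Region:
    try:
        return Region(
            str(entry.get("label", label)),
            int(entry["x0"]),
            int(entry["y0"]),
            int(entry["x1"]),
            int(entry["y1"]),
        )
    except KeyError as exc:
        raise ValueError(f"rectangle entry missing key {exc}") from exc


def _color_range(entry: dict) -> ColorRange:
    return ColorRange(tuple(int(v) for v in entry["low"]),
                      tuple(int(v) for v in entry["high"]))


def _calibration(entry: dict | None, image: np.ndarray | None) -> ColorCalibration:
    entry = entry or {"mode": "defaults"}
    mode = entry.get("mode", "defaults")
    if mode == "defaults":
        return default_calibration()
    if mode == "ranges":
        return ColorCalibration(
            background=_color_range(entry["background"]),
            tape=_color_range(entry["tape"]),
            tolerance=int(entry.get("tolerance", 10)),
        )
    if mode == "patches":
        if image is None:
            raise ValueError("patch calibration requires the input image")
        return calibrate_from_patches(
            image,
            _rect(entry["background_patch"], "background_patch"),
            _rect(entry["tape_patch"], "tape_patch"),
            tolerance=int(entry.get("tolerance", 10)),
        )
    raise ValueError(f"unknown calibration mode {mode!r}")


def load_run_config(path: str | Path, image: np.ndarray | None = None) -> RunConfig:
    """Parse and validate a YAML run config against an (optional) image."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config not found: {p}")
    raw = p.read_bytes()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    regions = tuple(
        _rect(entry, f"region{i}") for i, entry in enumerate(data.get("regions", []))
    )
    if not regions:
        raise ValueError("config defines no regions")

    overrides = []
    for entry in data.get("overrides", []):
        target = str(entry.get("class", "")).lower()
        if target not in ("background", "tape"):
            raise ValueError(f"override class must be background or tape, got {target!r}")
        overrides.append(
            OverrideAnnotation(_rect(entry, "override"), PixelClass[target.upper()])
        )

    refine = data.get("refine", {}) or {}
    return RunConfig(
        calibration=_calibration(data.get("calibration"), image),
        regions=regions,
        overrides=tuple(overrides),
        close_kernel=int(refine.get("close_kernel", 3)),
        speck_area_min=int(refine.get("speck_area_min", 3)),
        seed=int(data.get("seed", 0)),
        config_hash=hashlib.sha256(raw).hexdigest()[:16],
    )
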