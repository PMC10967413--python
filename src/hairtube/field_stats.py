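"""Field-validation statistics: aggregation, deduplication, correlation.

Implements the validation chain linking hair-tube densities to camera
observations: the two tape sides of a tube are averaged, the ten tubes
of a transect are averaged into one datapoint per (habitat, replicate,
repetition), camera sightings are deduplicated with a quiet-window
rule (default 10 min without any small-mammal presence before a new
sighting counts), both variables are Johnson-normalized, and Spearman
rank correlation is computed per habitat. Because Spearman operates on
ranks and every accepted Johnson fit is strictly increasing, the
transform cannot alter rho — both steps are implemented so the chain
matches the published protocol, and the rank invariance is checked in
the test suite.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .johnson import fit_johnson, johnson_transform

#: Taxa counted for the rodent-community activity index (rats and
#: shrews are recorded but excluded from validation).
DEFAULT_TAXA = frozenset({"Apodemus", "vole"})

#: 10 minutes in seconds.
DEFAULT_QUIET_WINDOW_S = 600.0

UNIT_KEYS = ["habitat", "replicate", "repetition"]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho with two-sided p-value; rho is NaN when undefined
    (zero rank variance in either variable)."""

    rho: float
    p_value: float
    n: int
    defined: bool = True


def average_tube(side_a: float | None, side_b: float | None) -> float:
    """Mean density of a tube's two tape sides; one missing side passes
    the other through unchanged. Both missing is an error (the caller
    excludes such tubes with a warning)."""
    present = [s for s in (side_a, side_b) if s is not None and not math.isnan(s)]
    if not present:
        raise ValueError("tube with both tape sides missing")
    return float(sum(present) / len(present))


def aggregate_transect(tube_means: Sequence[float]) -> float:
    """Unweighted mean over the tube averages of one transect repetition."""
    arr = [v for v in tube_means if v is not None and not math.isnan(v)]
    if not arr:
        raise ValueError("no usable tube records in transect")
    return float(sum(arr) / len(arr))


def aggregate_densities(tapes: pd.DataFrame) -> pd.DataFrame:
    """Two-stage density aggregation of a tapes table.

    Expects columns habitat, replicate, repetition, tube, side,
    density_percent (NaN = unreadable side). Tube sides are averaged
    first, then tubes within the transect repetition; tubes with no
    readable side are dropped with a warning. Returns one row per
    (habitat, replicate, repetition) with column ``mean_density``.
    """
    required = set(UNIT_KEYS + ["tube", "density_percent"])
    missing = required - set(tapes.columns)
    if missing:
        raise ValueError(f"tapes table lacks columns: {sorted(missing)}")
    per_tube = (
        tapes.groupby(UNIT_KEYS + ["tube"], sort=True)["density_percent"]
        .mean()  # NaN-skipping: single readable side stands alone
    )
    n_empty = int(per_tube.isna().sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} tube(s) had no readable tape side and were excluded",
            stacklevel=2,
        )
        per_tube = per_tube.dropna()
    out = (
        per_tube.groupby(level=UNIT_KEYS)
        .mean()
        .rename("mean_density")
        .reset_index()
    )
    return out


def dedupe_events(
    events: pd.DataFrame | Iterable[tuple[float, str]],
    quiet_window: float = DEFAULT_QUIET_WINDOW_S,
    taxa: frozenset[str] | set[str] = DEFAULT_TAXA,
    reset_on: str = "all",
) -> int:
    """Count independent sightings under the quiet-window rule.

    Scanning in time order, an event is counted iff at least
    ``quiet_window`` seconds passed since the preceding small-mammal
    event; the first event always counts. With ``reset_on="all"``
    (default) every event — counted or not, any taxon — restarts the
    window; with ``reset_on="counted"`` only events that passed the
    gap test do. Taxon filtering applies to the counted events, so a
    rat can silence a subsequent vole but is never itself counted.
    """
    if reset_on not in ("all", "counted"):
        raise ValueError("reset_on must be 'all' or 'counted'")
    if isinstance(events, pd.DataFrame):
        rows = list(zip(events["timestamp_s"], events["taxon"]))
    else:
        rows = list(events)
    rows.sort(key=lambda r: r[0])
    count = 0
    last: float | None = None
    for t, taxon in rows:
        passes = last is None or (t - last) >= quiet_window
        if passes and taxon in taxa:
            count += 1
        if reset_on == "all" or passes:
            last = t
    return count


def camera_counts(
    events: pd.DataFrame,
    quiet_window: float = DEFAULT_QUIET_WINDOW_S,
    taxa: frozenset[str] | set[str] = DEFAULT_TAXA,
    reset_on: str = "all",
) -> pd.DataFrame:
    """Deduplicated sighting counts per (habitat, replicate, repetition)."""
    if events.empty:
        return pd.DataFrame(columns=UNIT_KEYS + ["camera_count"])
    grouped = events.groupby(UNIT_KEYS, sort=True)
    rows = [
        dict(zip(UNIT_KEYS, key))
        | {"camera_count": dedupe_events(sub, quiet_window, taxa, reset_on)}
        for key, sub in grouped
    ]
    return pd.DataFrame(rows)


def build_datapoints(
    tapes: pd.DataFrame,
    events: pd.DataFrame,
    quiet_window: float = DEFAULT_QUIET_WINDOW_S,
    taxa: frozenset[str] | set[str] = DEFAULT_TAXA,
    reset_on: str = "all",
) -> pd.DataFrame:
    """Pair mean hair density with the deduplicated camera count per unit.

    Units present in the tapes table but without any camera event get a
    count of zero (the camera saw nothing, which is data, not missing).
    """
    densities = aggregate_densities(tapes)
    counts = camera_counts(events, quiet_window, taxa, reset_on)
    merged = densities.merge(counts, on=UNIT_KEYS, how="left")
    merged["camera_count"] = merged["camera_count"].fillna(0).astype(int)
    return merged


def spearman_test(x, y, method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on
    ties). ``method="t"`` uses the t-approximation with n-2 degrees of
    freedom (standard at the study's n = 40); ``method="exact"``
    enumerates all permutations (only for n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("Spearman test requires at least 3 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, defined=False)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        observed = abs(rho)
        hits = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            hits += abs(r) >= observed - 1e-12
            total += 1
        return CorrelationResult(rho, hits / total, n)
    if method != "t":
        raise ValueError("method must be 't' or 'exact'")

    if abs(rho) >= 1.0:
        return CorrelationResult(math.copysign(1.0, rho), 0.0, n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, p, n)


def validate_survey(
    tapes: pd.DataFrame,
    events: pd.DataFrame,
    quiet_window: float = DEFAULT_QUIET_WINDOW_S,
    taxa: frozenset[str] | set[str] = DEFAULT_TAXA,
    reset_on: str = "all",
    use_johnson: bool = True,
    min_points: int = 3,
) -> pd.DataFrame:
    """Per-habitat Spearman correlation of hair density vs camera count.

    Builds the aggregated datapoints, Johnson-normalizes each variable
    (skipped when a fit is impossible, e.g. near-constant counts), and
    runs the Spearman test separately per habitat. Returns a table with
    columns habitat, rho, p_value, n.
    """
    datapoints = build_datapoints(tapes, events, quiet_window, taxa, reset_on)
    rows = []
    for habitat, sub in datapoints.groupby("habitat", sort=True):
        if len(sub) < min_points:
            warnings.warn(
                f"habitat {habitat!r} has only {len(sub)} datapoints; skipped",
                stacklevel=2,
            )
            continue
        x = sub["mean_density"].to_numpy(dtype=float)
        y = sub["camera_count"].to_numpy(dtype=float)
        if use_johnson:
            x = _transform_or_identity(x)
            y = _transform_or_identity(y)
        result = spearman_test(x, y)
        rows.append(
            {
                "habitat": habitat,
                "rho": result.rho,
                "p_value": result.p_value,
                "n": result.n,
            }
        )
    return pd.DataFrame(rows, columns=["habitat", "rho", "p_value", "n"])


def _transform_or_identity(values: np.ndarray) -> np.ndarray:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_johnson(values)
        return johnson_transform(fit, values)
    except ValueError:
        return values
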