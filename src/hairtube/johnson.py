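"""Johnson-system normalization by the four-percentile (slice) method.

A Johnson transformation maps a sample to approximate normality with
one of three monotone families:

    SB (bounded):    z = gamma + delta * ln((x - xi) / (lambda + xi - x))
    SL (log-normal): z = gamma + delta * ln(x - xi)
    SU (unbounded):  z = gamma + delta * asinh((x - xi) / lambda)

Family and parameters are estimated from four symmetric sample
percentiles at normal quantiles -3z, -z, z, 3z (Slifker & Shapiro).
The ratio mn/p^2 of the outer to the squared inner percentile spread
selects the family; candidate fits over a grid of z values are scored
by the Shapiro-Wilk W statistic of the transformed sample and the best
candidate is returned, with the identity as fallback when no candidate
improves on the raw sample. All accepted fits are strictly increasing
on the sample range, so rank statistics are preserved exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["JohnsonFit", "fit_johnson", "johnson_transform"]


@dataclass(frozen=True)
class JohnsonFit:
    """Selected family with parameters and the achieved normality score."""

    family: str  # one of {"SB", "SL", "SU", "identity"}
    gamma: float = 0.0
    delta: float = 1.0
    lam: float = 1.0
    xi: float = 0.0
    normality_statistic: float = float("nan")  # Shapiro-Wilk W after transform


DEFAULT_Z_GRID = np.round(np.arange(0.25, 1.25 + 1e-9, 0.01), 2)


def _candidate(family: str, z: float, q: np.ndarray) -> JohnsonFit | None:
    """Parameter estimates from the four percentiles; None when invalid."""
    xm3, xm1, xp1, xp3 = q
    m = xp3 - xp1
    n = xm1 - xm3
    p = xp1 - xm1
    if min(m, n, p) <= 0:
        return None
    mid = 0.5 * (xp1 + xm1)
    qr = m * n / p**2

    if family == "SU":
        if qr <= 1.0:
            return None
        b = 0.5 * (m / p + n / p)
        delta = 2.0 * z / math.acosh(b)
        gamma = delta * math.asinh((n / p - m / p) / (2.0 * math.sqrt(qr - 1.0)))
        lam = (
            2.0 * p * math.sqrt(qr - 1.0)
            / ((m / p + n / p - 2.0) * math.sqrt(m / p + n / p + 2.0))
        )
        xi = mid + p * (n / p - m / p) / (2.0 * (m / p + n / p - 2.0))
        if delta <= 0 or lam <= 0:
            return None
        return JohnsonFit("SU", gamma, delta, lam, xi)

    if family == "SB":
        if qr >= 1.0:
            return None
        t = 0.5 * math.sqrt((1.0 + p / m) * (1.0 + p / n))
        if t <= 1.0:
            return None
        inv_qr = 1.0 / qr
        delta = z / math.acosh(t)
        gamma = delta * math.asinh(
            (p / n - p / m)
            * math.sqrt((1.0 + p / m) * (1.0 + p / n) - 4.0)
            / (2.0 * (inv_qr - 1.0))
        )
        lam = (
            p
            * math.sqrt(((1.0 + p / m) * (1.0 + p / n) - 2.0) ** 2 - 4.0)
            / (inv_qr - 1.0)
        )
        xi = mid - 0.5 * lam + p * (p / n - p / m) / (2.0 * (inv_qr - 1.0))
        if delta <= 0 or lam <= 0:
            return None
        return JohnsonFit("SB", gamma, delta, lam, xi)

    if family == "SL":
        r = m / p
        if r <= 1.0:  # positive skew form; mirror-image samples fall to SB/SU
            return None
        delta = 2.0 * z / math.log(r)
        gamma = delta * math.log((r - 1.0) / (p * math.sqrt(r)))
        xi = mid - 0.5 * p * (r + 1.0) / (r - 1.0)
        if delta <= 0:
            return None
        return JohnsonFit("SL", gamma, delta, 1.0, xi)

    raise ValueError(f"unknown family {family!r}")


def _in_domain(fit: JohnsonFit, values: np.ndarray) -> bool:
    if fit.family == "SB":
        return bool(
            np.all(values > fit.xi) and np.all(values < fit.xi + fit.lam)
        )
    if fit.family == "SL":
        return bool(np.all(values > fit.xi))
    return True  # SU and identity are defined everywhere


def johnson_transform(fit: JohnsonFit, values) -> np.ndarray:
    """Apply a fitted Johnson transform; errors name the offending value."""
    x = np.asarray(values, dtype=float)
    if fit.family == "identity":
        return x.copy()
    if not _in_domain(fit, x):
        bad = x[~_domain_mask(fit, x)][0]
        raise ValueError(
            f"value {bad} outside the {fit.family} domain "
            f"({_domain_text(fit)})"
        )
    if fit.family == "SB":
        u = (x - fit.xi) / (fit.lam + fit.xi - x)
        return fit.gamma + fit.delta * np.log(u)
    if fit.family == "SL":
        return fit.gamma + fit.delta * np.log(x - fit.xi)
    if fit.family == "SU":
        return fit.gamma + fit.delta * np.arcsinh((x - fit.xi) / fit.lam)
    raise ValueError(f"unknown family {fit.family!r}")


def _domain_mask(fit: JohnsonFit, x: np.ndarray) -> np.ndarray:
    if fit.family == "SB":
        return (x > fit.xi) & (x < fit.xi + fit.lam)
    if fit.family == "SL":
        return x > fit.xi
    return np.ones_like(x, dtype=bool)


def _domain_text(fit: JohnsonFit) -> str:
    if fit.family == "SB":
        return f"({fit.xi}, {fit.xi + fit.lam})"
    if fit.family == "SL":
        return f"({fit.xi}, inf)"
    return "(-inf, inf)"


def fit_johnson(sample, z_grid=None) -> JohnsonFit:
    """Select the Johnson fit maximizing Shapiro-Wilk W of the transform.

    For each z on the grid (default 0.25..1.25, step 0.01) all three
    families are attempted from the four percentiles at normal
    quantiles +-z, +-3z; candidates whose domain does not contain the
    sample are discarded. Falls back to the identity (with a warning)
    when no candidate beats the raw sample's W.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("Johnson fitting requires at least 8 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample cannot be normalized")
    grid = DEFAULT_Z_GRID if z_grid is None else np.asarray(z_grid, dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns on heavy ties
        raw_w = float(stats.shapiro(x).statistic)
    best = JohnsonFit("identity", normality_statistic=raw_w)
    n_valid = 0

    for z in grid:
        probs = stats.norm.cdf(np.array([-3.0, -1.0, 1.0, 3.0]) * z)
        q = np.quantile(x, probs)
        for family in ("SB", "SL", "SU"):
            try:
                cand = _candidate(family, float(z), q)
            except (ValueError, OverflowError, ZeroDivisionError):
                cand = None
            if cand is None or not _in_domain(cand, x):
                continue
            transformed = johnson_transform(cand, x)
            if not np.all(np.isfinite(transformed)) or np.ptp(transformed) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = float(stats.shapiro(transformed).statistic)
            n_valid += 1
            if w > best.normality_statistic:
                best = JohnsonFit(
                    cand.family, cand.gamma, cand.delta, cand.lam, cand.xi, w
                )
    if n_valid == 0:
        warnings.warn(
            "no valid Johnson candidate on the z grid; returning identity",
            stacklevel=2,
        )
    return best
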