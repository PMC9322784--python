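"""Poincaré-plot variability descriptors for daily activity series.

A Poincaré plot scatters consecutive values of a time series, (xₙ, xₙ₊ᵢ)
with delay i (one day here by default).  An ellipse aligned with the
identity line summarises the cloud: the semi-axis perpendicular to the
identity line (SD1) measures short-term, day-to-day variability; the
semi-axis along it (SD2) measures long-term variability.  With sample
standard deviations,

    SD1 = (√2/2) · SD(xₙ − xₙ₊ᵢ)
    SD2 = √( 2·SD(x)² − ½·SD(xₙ − xₙ₊ᵢ)² )
    SD12 = SD1 / SD2
    AFE  = π · SD1 · SD2   (area of the fitting ellipse)

where SD(x) is the sample SD of the whole series.  In index mode with lag 1
this gives the identity SD1² + SD2² = 2·SD(x)² exactly.

Daily wearable data has gaps (days the tracker was not worn or synced).
Two pairing modes are provided: ``calendar`` (default) emits a pair only
when two records are exactly ``lag_days`` calendar days apart, so a pair
never spans a gap; ``index`` pairs consecutive retained records regardless
of their calendar spacing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ActivitySeries
from .exceptions import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

#: Descriptor names in canonical (table-column) order.
DESCRIPTOR_NAMES = ("avg", "sd", "sd1", "sd2", "sd12", "afe")


@dataclass(frozen=True)
class PoincareConfig:
    """Poincaré-plot settings.

    Parameters
    ----------
    lag_days
        The delay i between paired observations, in days (calendar mode)
        or positions (index mode).
    pairing_mode
        ``"calendar"`` — pairs must be exactly ``lag_days`` calendar days
        apart; ``"index"`` — pairs are ``lag_days`` positions apart.
    min_pairs
        Minimum number of lagged pairs required before descriptors are
        reported; guards against meaningless estimates from fragmentary
        series.
    """

    lag_days: int = 1
    pairing_mode: str = "calendar"
    min_pairs: int = 10

    def __post_init__(self):
        if self.lag_days < 1:
            raise ValidationError("lag_days must be >= 1")
        if self.pairing_mode not in ("calendar", "index"):
            raise ValidationError(f"unknown pairing_mode {self.pairing_mode!r}")
        if self.min_pairs < 2:
            raise ValidationError("min_pairs must be >= 2")


@dataclass(frozen=True)
class PoincareDescriptors:
    """Variability descriptors of one series.

    ``sd12`` is NaN when SD2 = 0 (the ratio is undefined, not zero).
    ``avg`` and ``sd`` are the plain mean and sample SD of all values.
    """

    avg: float
    sd: float
    sd1: float
    sd2: float
    sd12: float
    afe: float
    n_pairs: int


def lagged_pairs(series: ActivitySeries, config: PoincareConfig = PoincareConfig()) -> np.ndarray:
    """Return the (xₙ, xₙ₊ᵢ) pairs of a series as an (n_pairs, 2) array.

    May be empty; pair order follows series order.
    """
    x = series.values
    n = len(x)
    lag = config.lag_days
    if n == 0:
        raise ValidationError("series is empty")
    if config.pairing_mode == "index":
        if n <= lag:
            return np.empty((0, 2))
        return np.column_stack([x[:-lag], x[lag:]])
    # calendar mode: partner must be exactly `lag` days later
    target = series.dates + np.timedelta64(lag, "D")
    idx = np.searchsorted(series.dates, target)
    ok = (idx < n) & (series.dates[np.minimum(idx, n - 1)] == target)
    return np.column_stack([x[ok], x[idx[ok]]])


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) >= 2 else 0.0


def poincare_descriptors(
    series: ActivitySeries, config: PoincareConfig = PoincareConfig()
) -> PoincareDescriptors:
    """Compute AVG, SD, SD1, SD2, SD12 and AFE for one series.

    Raises
    ------
    InsufficientDataError
        When fewer than ``config.min_pairs`` lagged pairs are available;
        the exception carries the number of pairs found.
    """
    pairs = lagged_pairs(series, config)
    n_pairs = len(pairs)
    if n_pairs < config.min_pairs:
        raise InsufficientDataError(
            f"only {n_pairs} lagged pairs available, need {config.min_pairs}",
            n=n_pairs,
        )
    avg = float(np.mean(series.values))
    sd = _sample_sd(series.values)
    sd_diff = _sample_sd(pairs[:, 0] - pairs[:, 1])
    sd1 = math.sqrt(0.5) * sd_diff
    radicand = 2.0 * sd * sd - 0.5 * sd_diff * sd_diff
    if radicand < 0:
        logger.warning(
            "negative SD2 radicand (%.6g) for subject %s metric %s; clipping to 0",
            radicand,
            series.subject_id,
            series.metric,
        )
        radicand = 0.0
    sd2 = math.sqrt(radicand)
    sd12 = sd1 / sd2 if sd2 > 0 else math.nan
    afe = math.pi * sd1 * sd2
    return PoincareDescriptors(avg, sd, sd1, sd2, sd12, afe, n_pairs)


def ellipse_outline(
    desc: PoincareDescriptors, n_points: int = 720
) -> np.ndarray:
    """Points of the fitting ellipse in Poincaré (xₙ, xₙ₊ᵢ) coordinates.

    The ellipse is centred at (avg, avg) with semi-axis ``sd2`` along the
    identity line and ``sd1`` perpendicular to it.  Returns an
    (n_points, 2) array, or a single centre point when both axes are zero.
    """
    if n_points < 4:
        raise ValidationError("n_points must be >= 4")
    if desc.sd1 == 0 and desc.sd2 == 0:
        return np.array([[desc.avg, desc.avg]])
    theta = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    along = desc.sd2 * np.cos(theta)       # component on (1,1)/√2
    across = desc.sd1 * np.sin(theta)      # component on (−1,1)/√2
    inv_sqrt2 = math.sqrt(0.5)
    x = desc.avg + inv_sqrt2 * (along - across)
    y = desc.avg + inv_sqrt2 * (along + across)
    return np.column_stack([x, y])


def descriptor_table(
    series_iter,
    config: PoincareConfig = PoincareConfig(),
) -> tuple[pd.DataFrame, list[str]]:
    """Descriptor rows for many series; skips series with too few pairs.

    Returns the table (columns: subject_id, metric, n_days, n_pairs,
    avg, sd, sd1, sd2, sd12, afe) and a list of notes for skipped series.
    """
    rows, notes = [], []
    for series in series_iter:
        try:
            d = poincare_descriptors(series, config)
        except InsufficientDataError as err:
            notes.append(
                f"skipped {series.subject_id}/{series.metric}: {err} "
            )
            continue
        rows.append(
            {
                "subject_id": series.subject_id,
                "metric": series.metric,
                "n_days": len(series),
                "n_pairs": d.n_pairs,
                "avg": d.avg,
                "sd": d.sd,
                "sd1": d.sd1,
                "sd2": d.sd2,
                "sd12": d.sd12,
                "afe": d.afe,
            }
        )
    columns = ["subject_id", "metric", "n_days", "n_pairs", *DESCRIPTOR_NAMES]
    return pd.DataFrame(rows, columns=columns), notes
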