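"""Surge exposure classification for a daily count series.

Turns a raw daily post-count series into a binary surge/non-surge exposure
calendar.  A day is *exposed* (a surge day) when its previous-day ratio —
the day's count divided by the preceding day's count — is at or above a
chosen percentile (default the 95th) of all defined ratios.

Undefined values (the first day, and days whose previous-day count is
zero) are carried as NaN, excluded from the threshold computation, and
flagged as undefined exposure so downstream merges can drop them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TweetSeries",
    "ExposureCalendar",
    "nearest_rank_percentile",
    "denoise",
    "previous_day_ratio",
    "previous_day_difference",
    "classify_surge",
    "summarize_series",
]


@dataclass
class TweetSeries:
    """A contiguous daily count series.

    Parameters
    ----------
    dates
        Strictly consecutive calendar days (normalised to midnight).
    counts
        Non-negative integer count per day.
    denoised
        Optional noise-reduced counts on the same scale; ``None`` until
        :func:`denoise` is applied.
    """

    dates: pd.DatetimeIndex
    counts: np.ndarray
    denoised: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates).normalize()
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.dates) != len(self.counts):
            raise ValueError("dates and counts must have equal length")
        if len(self.dates) >= 2:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]")
            if not (deltas == np.timedelta64(1, "D")).all():
                raise ValueError("dates must be consecutive calendar days")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.denoised is not None:
            self.denoised = np.asarray(self.denoised, dtype=float)
            if len(self.denoised) != len(self.counts):
                raise ValueError("denoised must match counts in length")

    @property
    def values(self) -> np.ndarray:
        """The series used for exposure classification (denoised if present)."""
        return self.denoised if self.denoised is not None else self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"date": self.dates, "count": self.counts.astype(int)})
        if self.denoised is not None:
            out["denoised"] = self.denoised
        return out

    @classmethod
    def from_csv(cls, path) -> "TweetSeries":
        df = pd.read_csv(path)
        for col in ("date", "count"):
            if col not in df.columns:
                raise ValueError(f"tweet series CSV is missing column {col!r}")
        dates = pd.to_datetime(df["date"])
        denoised = df["denoised"].to_numpy() if "denoised" in df.columns else None
        return cls(pd.DatetimeIndex(dates), df["count"].to_numpy(), denoised)


@dataclass
class ExposureCalendar:
    """Date-keyed surge classification.

    ``exposed`` is a float array: 1.0 surge day, 0.0 non-surge day, NaN
    where the ratio is undefined.
    """

    dates: pd.DatetimeIndex
    ratio: np.ndarray
    threshold: float
    exposed: np.ndarray
    percentile: float = 95.0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates).normalize()
        self._index = {d: i for i, d in enumerate(self.dates)}

    def is_exposed(self, date) -> Optional[bool]:
        """Exposure status of *date*: True/False, or None if outside the
        calendar or undefined."""
        i = self._index.get(pd.Timestamp(date).normalize())
        if i is None:
            return None
        e = self.exposed[i]
        return None if math.isnan(e) else bool(e)

    @property
    def n_surge_days(self) -> int:
        return int(np.nansum(self.exposed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "ratio": self.ratio, "exposed": self.exposed}
        )


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the smallest observed value v such that at
    least ``percentile`` percent of the observations are <= v.

    NaNs are ignored.  With n defined values this is the element of rank
    ceil(percentile/100 * n) in the sorted sequence.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    v = np.asarray(values, dtype=float)
    v = np.sort(v[~np.isnan(v)])
    if v.size == 0:
        raise ValueError("no defined values")
    rank = math.ceil(percentile / 100.0 * v.size)
    return float(v[max(rank, 1) - 1])


def denoise(series: TweetSeries, window_days: int) -> TweetSeries:
    """Detrend a count series by a centered moving median.

    Each day's count is divided by the centered moving median over
    ``window_days`` (truncated at the edges) and rescaled by the global
    median, so the output stays on the count scale.  ``window_days=0``
    disables denoising and returns the counts unchanged.
    """
    if window_days < 0 or (window_days > 0 and window_days % 2 == 0):
        raise ValueError("window_days must be odd and >= 1, or 0 to disable")
    counts = series.counts
    if not counts.any():
        raise ValueError("cannot denoise an all-zero series: no baseline")
    if window_days == 0:
        return TweetSeries(series.dates, counts, counts.copy())
    local = (
        pd.Series(counts)
        .rolling(window_days, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    scale = float(np.median(counts))
    with np.errstate(divide="ignore", invalid="ignore"):
        den = np.where(local > 0, counts / local * scale, 0.0)
    return TweetSeries(series.dates, counts, den)


def previous_day_ratio(values: np.ndarray) -> np.ndarray:
    """x(d) / x(d-1); NaN for the first day and wherever x(d-1) == 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    out = np.full(x.size, np.nan)
    prev = x[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = x[1:] / prev
    out[1:] = np.where(prev > 0, r, np.nan)
    return out


def previous_day_difference(values: np.ndarray) -> np.ndarray:
    """x(d) - x(d-1); NaN for the first day."""
    x = np.asarray(values, dtype=float)
    out = np.full(x.size, np.nan)
    out[1:] = np.diff(x)
    return out


def classify_surge(
    series: TweetSeries,
    percentile: float = 95.0,
    ratios: Optional[np.ndarray] = None,
) -> ExposureCalendar:
    """Classify each day as surge/non-surge by percentile thresholding of
    the previous-day ratio.

    The threshold is the nearest-rank ``percentile`` of the defined
    ratios; a day is exposed when its ratio is *at or above* the
    threshold.  Days with undefined ratios keep undefined exposure.
    A user-supplied ``ratios`` array (e.g. from an external noise
    reduction) overrides the internally computed one.
    """
    if ratios is None:
        ratios = previous_day_ratio(series.values)
    ratios = np.asarray(ratios, dtype=float)
    defined = ~np.isnan(ratios)
    if defined.sum() < 20:
        raise ValueError(
            f"need at least 20 defined ratios to set a percentile threshold, "
            f"got {int(defined.sum())}"
        )
    threshold = nearest_rank_percentile(ratios, percentile)
    exposed = np.full(ratios.size, np.nan)
    exposed[defined] = (ratios[defined] >= threshold).astype(float)
    return ExposureCalendar(series.dates, ratios, threshold, exposed, percentile)


def summarize_series(
    series: TweetSeries,
    ratios: Optional[np.ndarray] = None,
    diffs: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Quantile table (min, 5/25/50/95th percentiles, max) for the counts,
    the previous-day difference and the previous-day ratio, using the same
    nearest-rank rule as the surge classifier."""
    x = series.values
    if ratios is None:
        ratios = previous_day_ratio(x)
    if diffs is None:
        diffs = previous_day_difference(x)
    rows = {}
    for name, v in (("tweets", x), ("previous_day_difference", diffs), ("previous_day_ratio", ratios)):
        v = np.asarray(v, dtype=float)
        d = v[~np.isnan(v)]
        if d.size == 0:
            raise ValueError(f"no defined values in sequence {name!r}")
        rows[name] = {
            "min": float(d.min()),
            "p5": nearest_rank_percentile(d, 5),
            "p25": nearest_rank_percentile(d, 25),
            "p50": nearest_rank_percentile(d, 50),
            "p95": nearest_rank_percentile(d, 95),
            "max": float(d.max()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
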