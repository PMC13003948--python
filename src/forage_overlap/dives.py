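"""Dive detection, surface-interval bookkeeping, dive–fix linking and depth use.

A dive is a maximal run of consecutive depth samples >= 0.1 m lasting
>= 5 s; the periods between consecutive dives are surface intervals, and each
dive inherits the temporally last GPS fix of its immediately preceding
surface interval as its location (diving birds cannot acquire satellite
fixes, so every usable position is a surface position).

Gaps (NaN samples) in the trace conservatively break dive runs.  No
zero-offset drift correction is applied; a ``preprocess`` hook on
:class:`DiveDetector` accepts any caller-supplied depth correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DIVE_COLUMNS, SensorSeries, logger


@dataclass
class DepthHistogram:
    """Per-dive maximum depth binned in half-open classes [k*w, (k+1)*w)."""

    bin_width_m: float
    counts: np.ndarray
    total: int

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.counts.size + 1) * self.bin_width_m


class NonUniformSeriesError(ValueError):
    """Series is not uniformly sampled; resample or flag gaps as NaN first."""


def detect_dives(
    series: SensorSeries,
    min_depth_m: float = 0.1,
    min_duration_s: float = 5.0,
    preprocess: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Detect dives in a uniform depth trace.

    Returns a dive table (:data:`~forage_overlap.io.DIVE_COLUMNS`) with
    lon/lat NaN (linking happens later).  Maximal runs of samples with depth
    >= ``min_depth_m`` and length >= ``min_duration_s`` * rate become dives;
    max/mean depth are computed over the run.  NaN (gap) samples never belong
    to a dive run.
    """
    if min_depth_m <= 0 or min_duration_s <= 0:
        raise ValueError("detection thresholds must be positive")
    depth = series.depth_m
    if preprocess is not None:
        depth = np.asarray(preprocess(depth), dtype=float)
        if depth.shape != series.depth_m.shape:
            raise NonUniformSeriesError(
                "preprocess hook must preserve the sample grid; "
                "handle gaps by writing NaN, not by dropping samples"
            )
    rate = series.rate_hz
    with np.errstate(invalid="ignore"):
        mask = depth >= min_depth_m
    mask &= np.isfinite(depth)
    if not mask.any():
        return _empty_dive_table()

    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # exclusive
    min_samples = int(np.ceil(min_duration_s * rate))
    keep = (ends - starts) >= min_samples
    starts, ends = starts[keep], ends[keep]
    if starts.size == 0:
        return _empty_dive_table()

    step = np.timedelta64(int(round(1e9 / rate)), "ns")
    t0 = series.start
    rows = []
    for s, e in zip(starts, ends):
        seg = depth[s:e]
        rows.append(
            (
                series.bird_id,
                t0 + step * int(s),
                t0 + step * int(e),
                (e - s) / rate,
                float(seg.max()),
                float(seg.mean()),
                np.nan,
                np.nan,
            )
        )
    out = pd.DataFrame(rows, columns=DIVE_COLUMNS)
    return out


def _empty_dive_table() -> pd.DataFrame:
    df = pd.DataFrame(columns=DIVE_COLUMNS)
    return df.astype({"start": "datetime64[ns]", "end": "datetime64[ns]"}, errors="ignore")


def build_surface_intervals(
    dives: pd.DataFrame,
    span: tuple[np.datetime64, np.datetime64],
    fixes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition non-diving time into surface intervals and assign fixes.

    ``n`` dives yield ``n + 1`` intervals including the leading and trailing
    ones.  Returns ``(intervals, fixes)`` where fixes gains an
    ``interval_idx`` column; fixes timestamped inside a dive are physically
    implausible, dropped, and counted in the log.
    """
    dives = dives.sort_values("start").reset_index(drop=True)
    starts_arr = dives["start"].to_numpy() if len(dives) else np.array([], dtype="datetime64[ns]")
    ends_arr = dives["end"].to_numpy() if len(dives) else np.array([], dtype="datetime64[ns]")
    if len(dives) and (starts_arr[1:] < ends_arr[:-1]).any():
        raise ValueError("overlapping dives: surface intervals are undefined")

    lo = np.concatenate(([np.datetime64(span[0], "ns")], ends_arr))
    hi = np.concatenate((starts_arr, [np.datetime64(span[1], "ns")]))
    intervals = pd.DataFrame({"start": lo, "end": hi})

    fixes = fixes.sort_values("timestamp").reset_index(drop=True).copy()
    if len(fixes) == 0:
        fixes["interval_idx"] = np.array([], dtype=int)
        return intervals, fixes
    ts = fixes["timestamp"].to_numpy()
    # interval i spans [lo[i], hi[i]]; a fix inside a dive falls in (hi[i], lo[i+1])
    idx = np.searchsorted(lo, ts, side="right") - 1
    idx = np.clip(idx, 0, len(intervals) - 1)
    in_interval = ts <= hi[idx]
    n_rejected = int((~in_interval).sum())
    if n_rejected:
        logger.warning("%d fix(es) timestamped during a dive were rejected", n_rejected)
    fixes = fixes[in_interval].copy()
    fixes["interval_idx"] = idx[in_interval]
    return intervals, fixes


def link_dives(dives: pd.DataFrame, intervals: pd.DataFrame, fixes: pd.DataFrame) -> pd.DataFrame:
    """Assign each dive the last fix of its preceding surface interval.

    Dive ``k`` (time order) is preceded by interval ``k``; if that interval
    holds no fix the dive stays unlocated (lon/lat NaN).
    """
    dives = dives.sort_values("start").reset_index(drop=True).copy()
    dives[["lon", "lat"]] = np.nan
    if len(fixes) == 0 or len(dives) == 0:
        return dives
    last_fix = fixes.groupby("interval_idx").tail(1).set_index("interval_idx")
    hit = dives.index.intersection(last_fix.index)
    dives.loc[hit, "lon"] = last_fix.loc[hit, "lon"].to_numpy()
    dives.loc[hit, "lat"] = last_fix.loc[hit, "lat"].to_numpy()
    return dives


def depth_histogram(dives: pd.DataFrame, bin_width_m: float = 5.0) -> DepthHistogram:
    """Histogram of per-dive maximum depth in half-open ``bin_width_m`` classes."""
    if bin_width_m <= 0:
        raise ValueError("bin width must be positive")
    depths = dives["max_depth_m"].to_numpy(dtype=float)
    if depths.size == 0:
        return DepthHistogram(bin_width_m, np.zeros(0, dtype=int), 0)
    nbins = int(np.floor(depths.max() / bin_width_m)) + 1
    idx = np.floor(depths / bin_width_m).astype(int)
    counts = np.bincount(idx, minlength=nbins)
    return DepthHistogram(bin_width_m, counts, int(depths.size))


def share_below(dives: pd.DataFrame, threshold_m: float) -> float:
    """Percentage of dives whose maximum depth is <= ``threshold_m``."""
    if len(dives) == 0:
        raise ValueError("depth share undefined for an empty dive table")
    depths = dives["max_depth_m"].to_numpy(dtype=float)
    return 100.0 * float(np.mean(depths <= threshold_m))


class DiveDetector(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around dive detection.

    Parameters
    ----------
    min_depth_m, min_duration_s
        Detection thresholds (defaults 0.1 m / 5 s).
    preprocess
        Optional depth-correction hook applied before thresholding (e.g. a
        zero-offset drift correction); must preserve the sample grid.
    """

    def __init__(self, min_depth_m: float = 0.1, min_duration_s: float = 5.0,
                 preprocess: Callable | None = None):
        self.min_depth_m = min_depth_m
        self.min_duration_s = min_duration_s
        self.preprocess = preprocess

    def fit(self, X=None, y=None):
        if self.min_depth_m <= 0 or self.min_duration_s <= 0:
            raise ValueError("detection thresholds must be positive")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        """Detect dives in one :class:`SensorSeries` or a dict of them."""
        self.fit()
        if isinstance(X, SensorSeries):
            X = {X.bird_id: X}
        tables = [
            detect_dives(s, self.min_depth_m, self.min_duration_s, self.preprocess)
            for s in X.values()
        ]
        tables = [t for t in tables if len(t)]
        if not tables:
            return _empty_dive_table()
        return pd.concat(tables, ignore_index=True)
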