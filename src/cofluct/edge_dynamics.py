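"""Edge time series (eTS), RSS co-fluctuation amplitude, and its temporal summaries.

For z-scored parcel signals z_i(t), the edge time series of the pair (i, j)
is the frame-wise product z_i(t)·z_j(t); its time average (population
convention) equals the Pearson correlation of the two parcels. The root sum
square (RSS) over all N(N-1)/2 edges at each frame is a scalar index of
whole-brain co-fluctuation amplitude. Two temporal summaries are derived
from the RSS:

* mean trough-to-trough duration (in TR units) — how fast the brain moves
  between low-co-fluctuation states;
* mean peak height — the typical amplitude of co-fluctuation events.

Extremum rule: frame t is a trough iff values[t-1] > values[t] < values[t+1]
(peak analogous); plateaus collapse to their first frame; the endpoints of
the series are never extrema.

For large parcellations the RSS is computed without materializing the full
E × T edge matrix, using the identity
``RSS(t)^2 = ((Σ_i z_i^2)^2 − Σ_i z_i^4) / 2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from cofluct.io import ParcelSignals, UndefinedMetricError, ValidationError

logger = logging.getLogger("cofluct")

__all__ = [
    "EdgeTimeSeries",
    "RSSSeries",
    "DynamicsSummary",
    "edge_time_series",
    "rss",
    "rss_from_signals",
    "find_extrema",
    "mean_trough_duration",
    "mean_peak_height",
    "select_amplitude_frames",
    "dynamics_summary",
]

#: Above this many edge-matrix elements (E·T) the RSS is computed via the
#: power-sum identity instead of materializing the eTS. Both paths agree to
#: machine precision; this is purely a memory guard.
STREAMING_THRESHOLD = 20_000_000


def _check_zscored(data: np.ndarray, tol: float = 1e-6) -> None:
    mu = np.abs(data.mean(axis=0)).max()
    sd = np.abs(data.std(axis=0) - 1.0).max()
    if mu > tol or sd > tol:
        raise ValidationError(
            f"input not z-scored (max |mean| {mu:.2e}, max |sd-1| {sd:.2e}); "
            "apply preprocess.zscore first")


@dataclass
class EdgeTimeSeries:
    """E × T edge matrix; row k is the product series of edge_index[k]."""

    data: np.ndarray
    edge_index: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.edge_index):
            raise ValidationError("edge_index does not match edge rows")


@dataclass
class RSSSeries:
    """Per-frame co-fluctuation amplitude with located peaks and troughs."""

    values: np.ndarray
    peak_indices: np.ndarray
    trough_indices: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("RSS values must be non-negative")


@dataclass
class DynamicsSummary:
    subject_id: str
    mean_trough_duration: float  # TR units
    n_durations: int
    mean_peak_height: float
    n_peaks: int


def edge_time_series(z: ParcelSignals) -> EdgeTimeSeries:
    """All pairwise product series, ordered row-major over i < j."""
    _check_zscored(z.data)
    n = z.n_parcels
    iu, ju = np.triu_indices(n, k=1)
    data = (z.data[:, iu] * z.data[:, ju]).T  # E × T
    edge_index = [(z.parcel_ids[i], z.parcel_ids[j]) for i, j in zip(iu, ju)]
    return EdgeTimeSeries(data, edge_index)


def _rss_values_from_z(zdata: np.ndarray) -> np.ndarray:
    s2 = (zdata ** 2).sum(axis=1)
    s4 = (zdata ** 4).sum(axis=1)
    return np.sqrt(np.maximum(s2 ** 2 - s4, 0.0) / 2.0)


def rss(ets: EdgeTimeSeries, tr: float) -> RSSSeries:
    """Root-sum-square over edges at each frame, with extrema located."""
    if ets.data.shape[0] < 1:
        raise ValidationError("need at least one edge")
    values = np.sqrt((ets.data ** 2).sum(axis=0))
    peaks, troughs = find_extrema(values)
    return RSSSeries(values, peaks, troughs, tr)


def rss_from_signals(z: ParcelSignals) -> RSSSeries:
    """RSS directly from z-scored signals.

    Uses the power-sum identity when the implied edge matrix would be large;
    numerically identical to the edge-wise path either way.
    """
    _check_zscored(z.data)
    e = z.n_parcels * (z.n_parcels - 1) // 2
    if e * z.n_frames > STREAMING_THRESHOLD:
        values = _rss_values_from_z(z.data)
    else:
        ets = edge_time_series(z)
        values = np.sqrt((ets.data ** 2).sum(axis=0))
    peaks, troughs = find_extrema(values)
    return RSSSeries(values, peaks, troughs, z.tr)


def find_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima and minima with plateau collapse.

    A run of equal values counts as a single candidate anchored at its first
    frame; it is a peak (trough) iff the distinct neighbours on both sides
    are lower (higher). Endpoint runs are never extrema.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate([[0], change + 1])   # first index of each run
    rv = v[starts]                               # run values
    if rv.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    mid = slice(1, rv.size - 1)
    peak_runs = (rv[1:-1] > rv[:-2]) & (rv[1:-1] > rv[2:])
    trough_runs = (rv[1:-1] < rv[:-2]) & (rv[1:-1] < rv[2:])
    peaks = starts[mid][peak_runs]
    troughs = starts[mid][trough_runs]
    return peaks, troughs


def mean_trough_duration(r: RSSSeries) -> tuple[float, int]:
    """Mean frames (TR units) between successive RSS troughs.

    Returns ``(mean_duration, n_durations)``; raises
    :class:`UndefinedMetricError` with fewer than two troughs so the caller
    can flag (not silently drop) the subject.
    """
    if r.trough_indices.size == 0:
        raise UndefinedMetricError("no troughs in RSS series")
    if r.trough_indices.size < 2:
        raise UndefinedMetricError("fewer than 2 troughs; duration undefined")
    durations = np.diff(r.trough_indices).astype(float)
    return float(durations.mean()), int(durations.size)


def mean_peak_height(r: RSSSeries) -> tuple[float, int]:
    """Mean RSS value at the detected peaks. Returns ``(mean, n_peaks)``."""
    if r.peak_indices.size == 0:
        raise UndefinedMetricError("no peaks in RSS series")
    return float(r.values[r.peak_indices].mean()), int(r.peak_indices.size)


def select_amplitude_frames(r: RSSSeries, fraction: float, side: str,
                            on_extrema: bool = False) -> np.ndarray:
    """Frames with the largest ("high") or smallest ("low") RSS.

    Selects ``ceil(fraction · T)`` frames ranked by RSS value, ties broken
    toward the earlier frame, returned sorted ascending. With
    ``on_extrema=True`` the ranking is restricted to detected peak (high) or
    trough (low) frames — the alternative reading of "top/bottom 10%
    peaks/troughs".
    """
    if side not in ("high", "low"):
        raise ValueError("side must be 'high' or 'low'")
    if not 0 < fraction <= 0.5:
        raise ValidationError("fraction must lie in (0, 0.5]")
    t = r.values.size
    k = math.ceil(fraction * t)
    if k < 3:
        raise ValidationError(
            f"fraction {fraction} of {t} frames selects only {k} (< 3)")
    if on_extrema:
        pool = r.peak_indices if side == "high" else r.trough_indices
        if pool.size < k:
            raise ValidationError(
                f"only {pool.size} {side}-extremum frames for k={k}")
    else:
        pool = np.arange(t)
    vals = r.values[pool]
    if np.all(vals == vals[0]):
        logger.warning("constant RSS: amplitude selection falls back to the "
                       "first %d frames for side=%s", k, side)
    key = -vals if side == "high" else vals
    order = np.lexsort((pool, key))  # value first, earlier frame on ties
    return np.sort(pool[order[:k]])


def dynamics_summary(z: ParcelSignals) -> DynamicsSummary:
    """Per-subject RSS temporal summary from z-scored signals."""
    r = rss_from_signals(z)
    dur, n_dur = mean_trough_duration(r)
    height, n_peaks = mean_peak_height(r)
    return DynamicsSummary(z.subject_id, dur, n_dur, height, n_peaks)
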