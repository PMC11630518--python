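"""Pairwise time-delay (TD) estimation from lagged cross-covariance.

For z-scored series the lagged cross-covariance is

    c_ij(Δ) = (1 / (T − |Δ|)) Σ_t z_i(t) · z_j(t + Δ),   Δ = −L..L (TR units),

so a positive peak lag means parcel i *leads* parcel j (j is a delayed copy
of i). The per-lag overlap normalization avoids the systematic bias toward
lag 0 that an unnormalized sum would introduce.

The sub-TR delay τ̂ is the integer peak lag plus a three-point parabolic
refinement around the extremum of |c(Δ)|:

    τ̂ = TR · [ Δ_peak + (c_{peak−1} − c_{peak+1}) /
                          (2 (c_{peak−1} − 2 c_peak + c_{peak+1})) ].

Anticorrelated pairs contribute via their negative extremum; the same
formula applies to the signed values around it. Extrema at the search
boundary and flat (zero-curvature) extrema skip interpolation, keep the
integer-lag estimate, and are flagged so callers can report a per-subject
boundary fraction rather than silently dropping pairs.

Sign convention of the TD matrix: entry [i, j] is the time (seconds) by
which parcel j's signal *precedes* parcel i's. The matrix is antisymmetric
by construction, and column-averaging it (the projection map) assigns
positive values to parcels whose signal leads the rest of the brain
(positive = early propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cofluct.io import NetworkPartition, ParcelSignals, ValidationError

logger = logging.getLogger("cofluct")

__all__ = [
    "LaggedCCF",
    "TauEstimate",
    "TDMatrix",
    "ProjectionMap",
    "lagged_crosscov",
    "parabolic_tau",
    "td_matrix",
    "projection_map",
    "network_td",
    "network_td_from_signals",
]

FLAT_TOL = 1e-12


@dataclass
class LaggedCCF:
    """Cross-covariance on the symmetric integer lag grid −L..L (TR units)."""

    lags: np.ndarray
    values: np.ndarray
    peak_lag: int
    boundary_flag: bool

    def __post_init__(self) -> None:
        if self.lags.size != self.values.size or self.lags.size % 2 != 1:
            raise ValidationError("lag grid must be odd-length and aligned")


@dataclass
class TauEstimate:
    tau_seconds: float
    flag: str | None = None  # None | "boundary" | "flat" | "clamped"


@dataclass
class TDMatrix:
    """Antisymmetric N × N pairwise delay matrix in seconds.

    ``data[i, j]`` = lead of parcel j over parcel i. ``flags`` holds, per
    unordered pair position (upper triangle), the estimation flag.
    """

    data: np.ndarray
    parcel_ids: list[str]
    boundary_fraction: float = 0.0
    flagged_pairs: int = 0


@dataclass
class ProjectionMap:
    """Column-averaged TD per parcel (seconds); positive = early propagation."""

    values: np.ndarray
    parcel_ids: list[str]


def _check_pair_length(t: int, max_lag: int) -> None:
    if t <= 2 * max_lag + 4:
        raise ValidationError(
            f"series length {t} insufficient for max lag {max_lag} "
            f"(need T > {2 * max_lag + 4})")


def lagged_crosscov(x_i: np.ndarray, x_j: np.ndarray, max_lag: int) -> LaggedCCF:
    """Overlap-normalized cross-covariance of two z-scored series.

    ``peak_lag`` maximizes |c(Δ)|; ``boundary_flag`` is set when the peak
    sits at ±max_lag.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    t = x_i.size
    _check_pair_length(t, max_lag)
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.empty(lags.size)
    for k, d in enumerate(lags):
        if d >= 0:
            values[k] = x_i[: t - d] @ x_j[d:] / (t - d)
        else:
            values[k] = x_i[-d:] @ x_j[: t + d] / (t + d)
    peak_pos = int(np.argmax(np.abs(values)))
    peak_lag = int(lags[peak_pos])
    return LaggedCCF(lags, values, peak_lag, abs(peak_lag) == max_lag)


def _parabolic_fraction(c_m: float, c_0: float, c_p: float) -> tuple[float, str | None]:
    denom = 2.0 * (c_m - 2.0 * c_0 + c_p)
    if abs(c_m - 2.0 * c_0 + c_p) < FLAT_TOL:
        return 0.0, "flat"
    frac = (c_m - c_p) / denom
    if abs(frac) > 0.5:
        return float(np.clip(frac, -0.5, 0.5)), "clamped"
    return frac, None


def parabolic_tau(ccf: LaggedCCF, tr: float) -> TauEstimate:
    """Sub-TR delay from three-point parabolic interpolation at the CCF extremum.

    At a boundary peak the interpolation is skipped and τ̂ = peak_lag · TR
    with a "boundary" flag; a flat curvature likewise keeps the integer lag.
    The fractional part is clamped to ±TR/2 (with a flag) if the three
    points ever imply a vertex outside the central bin.
    """
    if ccf.boundary_flag:
        return TauEstimate(ccf.peak_lag * tr, "boundary")
    pos = int(ccf.peak_lag - ccf.lags[0])
    c_m, c_0, c_p = ccf.values[pos - 1], ccf.values[pos], ccf.values[pos + 1]
    frac, flag = _parabolic_fraction(c_m, c_0, c_p)
    if flag == "flat":
        return TauEstimate(ccf.peak_lag * tr, "flat")
    if flag == "clamped":
        logger.warning("parabolic vertex beyond ±TR/2 clamped (peak lag %d)",
                       ccf.peak_lag)
    return TauEstimate((ccf.peak_lag + frac) * tr, flag)


def pair_delay(x_i: np.ndarray, x_j: np.ndarray, max_lag: int,
               tr: float) -> TauEstimate:
    """Delay of pair (i, j): positive τ̂ means x_i leads x_j."""
    return parabolic_tau(lagged_crosscov(x_i, x_j, max_lag), tr)


def _stacked_crosscov(zdata: np.ndarray, max_lag: int) -> np.ndarray:
    """C[Δ + L, i, j] = mean_t z_i(t) · z_j(t + Δ) for Δ = −L..L."""
    t, n = zdata.shape
    c = np.empty((2 * max_lag + 1, n, n))
    for d in range(max_lag + 1):
        m = zdata[: t - d].T @ zdata[d:] / (t - d)
        c[max_lag + d] = m
        c[max_lag - d] = m.T
    return c


def td_matrix(z: ParcelSignals, max_lag: int) -> TDMatrix:
    """Pairwise delays for every unordered parcel pair, vectorized.

    Each pair is estimated once and its negation fills the mirror entry, so
    antisymmetry holds exactly. Boundary/flat pairs keep their integer-lag
    estimate and are counted, never dropped.
    """
    from cofluct.edge_dynamics import _check_zscored

    _check_zscored(z.data)
    _check_pair_length(z.n_frames, max_lag)
    n = z.n_parcels
    c = _stacked_crosscov(z.data, max_lag)
    iu, ju = np.triu_indices(n, k=1)
    vals = c[:, iu, ju]                       # (2L+1) × P
    peak_pos = np.argmax(np.abs(vals), axis=0)
    peak_lag = peak_pos - max_lag
    boundary = np.abs(peak_lag) == max_lag

    p = np.arange(vals.shape[1])
    interior = ~boundary
    frac = np.zeros(vals.shape[1])
    flat = np.zeros(vals.shape[1], dtype=bool)
    if interior.any():
        pi = peak_pos[interior]
        cols = p[interior]
        c_m = vals[pi - 1, cols]
        c_0 = vals[pi, cols]
        c_p = vals[pi + 1, cols]
        curv = c_m - 2.0 * c_0 + c_p
        flat_i = np.abs(curv) < FLAT_TOL
        f = np.zeros(cols.size)
        ok = ~flat_i
        f[ok] = (c_m[ok] - c_p[ok]) / (2.0 * curv[ok])
        n_clamped = int(np.sum(np.abs(f) > 0.5))
        if n_clamped:
            logger.warning("%d pair(s) clamped to ±TR/2 fractional lag", n_clamped)
        f = np.clip(f, -0.5, 0.5)
        frac[interior] = f
        flat[interior] = flat_i
    tau = (peak_lag + frac) * z.tr            # lead of i over j, seconds

    data = np.zeros((n, n))
    data[iu, ju] = -tau                       # [i, j] = lead of j over i
    data[ju, iu] = tau
    n_pairs = iu.size
    return TDMatrix(
        data, list(z.parcel_ids),
        boundary_fraction=float(boundary.sum() / n_pairs),
        flagged_pairs=int(boundary.sum() + flat.sum()),
    )


def projection_map(td: TDMatrix) -> ProjectionMap:
    """Column-wise average over the off-diagonal entries.

    Positive values mark parcels whose signal leads the brain-wide average
    (early propagation); the map averages to zero over parcels as a
    consequence of antisymmetry.
    """
    n = td.data.shape[0]
    values = td.data.sum(axis=0) / (n - 1)
    return ProjectionMap(values, list(td.parcel_ids))


def network_td(pm: ProjectionMap, part: NetworkPartition, network: str) -> float:
    """Unweighted mean of the projection map over one network's parcels."""
    members = set(part.parcels(network))
    idx = [k for k, p in enumerate(pm.parcel_ids) if p in members]
    if not idx:
        raise ValidationError(f"network {network!r} has no parcels in the map")
    return float(pm.values[idx].mean())


def network_td_from_signals(z: ParcelSignals, part: NetworkPartition,
                            max_lag: int, network: str = "SMN"
                            ) -> tuple[float, float]:
    """Convenience chain: TD matrix → projection map → network mean.

    Returns ``(network_td_seconds, boundary_fraction)``.
    """
    td = td_matrix(z, max_lag)
    pm = projection_map(td)
    return network_td(pm, part, network), td.boundary_fraction
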