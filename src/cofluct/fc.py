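"""Static and amplitude-conditioned SMN–DMN functional connectivity.

Static FC is the Pearson correlation matrix over all frames; the
inter-network connection is the unweighted mean of the raw correlations
over every SMN × DMN parcel pair (no Fisher transform by default).

High-/low-amplitude FC restricts the correlation to the frames with the
largest / smallest whole-brain co-fluctuation amplitude (top and bottom
10% of RSS frames by default). Means and SDs are recomputed within the
frame subset — the conditional FC is a fresh correlation on those frames,
not a re-weighting of the full-series moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from cofluct.edge_dynamics import RSSSeries, select_amplitude_frames
from cofluct.io import NetworkPartition, ParcelSignals, ValidationError

logger = logging.getLogger("cofluct")

__all__ = [
    "FCMatrix",
    "InternetworkSummary",
    "static_fc",
    "internetwork_mean",
    "amplitude_fc",
    "internetwork_summary",
]


@dataclass
class FCMatrix:
    """Pearson correlation matrix over a (possibly restricted) frame set."""

    data: np.ndarray
    parcel_ids: list[str]
    n_frames: int
    frame_set: np.ndarray | None = None
    flagged_parcels: list[str] = field(default_factory=list)


@dataclass
class InternetworkSummary:
    subject_id: str
    fc_static: float
    fc_high: float
    fc_low: float
    n_pairs: int
    n_frames_high: int
    n_frames_low: int


def static_fc(ps: ParcelSignals, frames: np.ndarray | None = None) -> FCMatrix:
    """Pearson correlation across parcels over the selected frames.

    ``frames=None`` uses all frames. A parcel with zero variance within the
    frame subset gets correlation 0 with every other parcel (diagonal stays
    1) and is flagged, so the pair count stays constant across subjects.
    """
    if frames is None:
        x = ps.data
        frame_set = None
    else:
        frames = np.asarray(frames, dtype=int)
        if frames.size < 3:
            raise ValidationError(f"need >= 3 frames, got {frames.size}")
        if frames.min() < 0 or frames.max() >= ps.n_frames:
            raise ValidationError("frame index out of range")
        x = ps.data[frames]
        frame_set = frames
    t = x.shape[0]
    xc = x - x.mean(axis=0)
    sd = x.std(axis=0)
    zero = sd == 0
    flagged = [ps.parcel_ids[i] for i in np.flatnonzero(zero)]
    if flagged:
        logger.warning("zero-variance parcels in frame subset: %s", flagged)
    safe_sd = np.where(zero, 1.0, sd)
    zn = xc / safe_sd
    corr = zn.T @ zn / t
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return FCMatrix(corr, list(ps.parcel_ids), t, frame_set, flagged)


def internetwork_mean(fc: FCMatrix, part: NetworkPartition,
                      net_a: str = "SMN", net_b: str = "DMN",
                      fisher_z: bool = False) -> tuple[float, int]:
    """Unweighted mean correlation over all |A|·|B| cross-network pairs.

    Returns ``(mean_r, n_pairs)``. With ``fisher_z=True`` the averaging is
    done on the arctanh scale and transformed back (sensitivity analysis).
    """
    a = set(part.parcels(net_a))
    b = set(part.parcels(net_b))
    if not a or not b:
        raise ValidationError(f"networks {net_a}/{net_b} must be non-empty")
    if a & b:
        raise ValidationError(
            f"networks {net_a} and {net_b} overlap: {sorted(a & b)[:5]}")
    pos = {p: k for k, p in enumerate(fc.parcel_ids)}
    ia = [pos[p] for p in fc.parcel_ids if p in a]
    ib = [pos[p] for p in fc.parcel_ids if p in b]
    if not ia or not ib:
        raise ValidationError("networks not represented in the FC matrix")
    block = fc.data[np.ix_(ia, ib)]
    if fisher_z:
        z = np.arctanh(np.clip(block, -1 + 1e-12, 1 - 1e-12))
        return float(np.tanh(z.mean())), block.size
    return float(block.mean()), block.size


def amplitude_fc(ps: ParcelSignals, r: RSSSeries, part: NetworkPartition,
                 fraction: float = 0.10, net_a: str = "SMN",
                 net_b: str = "DMN", fisher_z: bool = False,
                 on_extrema: bool = False) -> tuple[float, float]:
    """Inter-network FC restricted to high- and low-amplitude frames.

    Returns ``(fc_high, fc_low)`` — the SMN–DMN mean correlation over the
    top- and bottom-``fraction`` RSS frames respectively.
    """
    hi = select_amplitude_frames(r, fraction, "high", on_extrema=on_extrema)
    lo = select_amplitude_frames(r, fraction, "low", on_extrema=on_extrema)
    fc_hi, _ = internetwork_mean(static_fc(ps, hi), part, net_a, net_b, fisher_z)
    fc_lo, _ = internetwork_mean(static_fc(ps, lo), part, net_a, net_b, fisher_z)
    return fc_hi, fc_lo


def internetwork_summary(ps: ParcelSignals, r: RSSSeries,
                         part: NetworkPartition, fraction: float = 0.10,
                         fisher_z: bool = False) -> InternetworkSummary:
    """Static, high- and low-amplitude SMN–DMN connection for one subject."""
    fc_all = static_fc(ps)
    stat, n_pairs = internetwork_mean(fc_all, part, fisher_z=fisher_z)
    hi = select_amplitude_frames(r, fraction, "high")
    lo = select_amplitude_frames(r, fraction, "low")
    fc_hi, _ = internetwork_mean(static_fc(ps, hi), part, fisher_z=fisher_z)
    fc_lo, _ = internetwork_mean(static_fc(ps, lo), part, fisher_z=fisher_z)
    return InternetworkSummary(ps.subject_id, stat, fc_hi, fc_lo,
                               n_pairs, hi.size, lo.size)
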