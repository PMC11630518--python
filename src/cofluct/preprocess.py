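"""Motion QC gates and signal-level cleaning for parcellated BOLD.

The cleaning chain applied after parcellation is fixed and logged:
linear detrend + zero-phase band-pass → nuisance regression → z-scoring.
Global-signal regression is deliberately never performed, as it would bias
the lag and co-fluctuation estimates downstream.

Frame-wise displacement (FD) follows Power's definition: the sum of the
absolute frame-to-frame differences of the six rigid-body parameters, with
rotations (radians) converted to arc length on a 50 mm sphere. The first
frame's FD is defined as 0 so the series has one value per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from cofluct.io import ParcelSignals, RunConfig, ValidationError

logger = logging.getLogger("cofluct")

__all__ = [
    "MotionSummary",
    "QCDecision",
    "compute_fd",
    "motion_exclude",
    "bandpass_detrend",
    "regress_nuisance",
    "zscore",
    "clean_signals",
]

HEAD_RADIUS_MM = 50.0

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class MotionSummary:
    subject_id: str
    fd_series: np.ndarray      # mm, length T, fd[0] == 0
    mean_fd: float             # mm, mean over frames 2..T
    spike_fraction: float      # fraction of all T frames with fd > threshold

    def __post_init__(self) -> None:
        self.fd_series = np.asarray(self.fd_series, dtype=float)
        if np.any(self.fd_series < 0):
            raise ValidationError("fd_series must be non-negative")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValidationError("spike_fraction must lie in [0, 1]")


@dataclass
class QCDecision:
    keep: bool
    reasons: list[str] = field(default_factory=list)


def compute_fd(motion_params: np.ndarray | pd.DataFrame,
               subject_id: str = "",
               spike_threshold: float = 0.25) -> MotionSummary:
    """Power-style FD from a T × 6 motion-parameter table.

    Columns: three translations (mm) then three rotations (radians).
    ``spike_threshold`` (mm) defines which frames count as spike volumes.
    """
    if isinstance(motion_params, pd.DataFrame):
        motion_params = motion_params.to_numpy()
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValidationError(
            f"motion parameters must be T × 6, got shape {mp.shape}")
    if mp.shape[0] < 2:
        raise ValidationError("need at least 2 frames to compute FD")
    diffs = np.abs(np.diff(mp, axis=0))
    diffs[:, 3:] *= HEAD_RADIUS_MM  # radians → arc length on 50 mm sphere
    fd = np.concatenate([[0.0], diffs.sum(axis=1)])
    mean_fd = float(fd[1:].mean())
    spike_fraction = float(np.mean(fd > spike_threshold))
    return MotionSummary(subject_id, fd, mean_fd, spike_fraction)


def motion_exclude(ms: MotionSummary, cfg: RunConfig) -> QCDecision:
    """Exclude iff mean FD > threshold OR spike fraction > threshold.

    Both inequalities are strict ("greater than 0.25 mm", "above 25%");
    sitting exactly on a threshold keeps the subject. Both reasons are
    reported when both criteria fire.
    """
    reasons = []
    if ms.mean_fd > cfg.fd_mean_threshold:
        reasons.append(
            f"mean FD {ms.mean_fd:.4g} mm > {cfg.fd_mean_threshold} mm")
    if ms.spike_fraction > cfg.fd_spike_fraction:
        reasons.append(
            f"spike fraction {ms.spike_fraction:.4g} > {cfg.fd_spike_fraction}")
    return QCDecision(keep=not reasons, reasons=reasons)


def bandpass_detrend(ps: ParcelSignals, low: float, high: float) -> ParcelSignals:
    """Linear detrend per parcel, then zero-phase Butterworth band-pass.

    The filter is a 4th-order Butterworth run forward-backward
    (``sosfiltfilt``) so it introduces no phase shift — essential because
    artificial lags would corrupt the time-delay estimates.
    """
    nyq = 1.0 / (2.0 * ps.tr)
    if not (0 < low < high < nyq):
        raise ValidationError(
            f"band ({low}, {high}) Hz infeasible: need 0 < low < high < "
            f"Nyquist {nyq:.4g} Hz for TR {ps.tr} s")
    x = sps.detrend(ps.data, axis=0, type="linear")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=1.0 / ps.tr,
                     output="sos")
    y = sps.sosfiltfilt(sos, x, axis=0)
    return ps.with_data(y)


def regress_nuisance(ps: ParcelSignals, confounds: np.ndarray | pd.DataFrame
                     ) -> ParcelSignals:
    """Residualize each parcel on the confound columns plus an intercept.

    The global signal is never added implicitly. Rank-deficient confound
    matrices trigger a warning and a pseudoinverse (minimum-norm) fit.
    """
    if isinstance(confounds, pd.DataFrame):
        confounds = confounds.to_numpy()
    c = np.asarray(confounds, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != ps.n_frames:
        raise ValidationError(
            f"confounds have {c.shape[0]} rows for {ps.n_frames} frames")
    design = np.column_stack([np.ones(ps.n_frames), c])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("confound matrix rank-deficient (rank %d of %d); "
                       "using pseudoinverse fit", rank, design.shape[1])
    beta = np.linalg.pinv(design) @ ps.data
    resid = ps.data - design @ beta
    return ps.with_data(resid)


def zscore(ps: ParcelSignals) -> ParcelSignals:
    """Per-parcel standardization with the population (denominator T) SD.

    The population convention makes the time-average of an edge product
    equal the Pearson correlation exactly, which downstream modules rely on.
    """
    mu = ps.data.mean(axis=0)
    sd = ps.data.std(axis=0)  # ddof=0
    # a numerically constant parcel has sd at rounding level, not exactly 0
    zero = np.flatnonzero(sd <= 1e-13 * np.maximum(1.0, np.abs(mu)))
    if zero.size:
        raise ValidationError(
            f"zero-variance parcel(s): {[ps.parcel_ids[i] for i in zero[:5]]}")
    return ps.with_data((ps.data - mu) / sd)


def clean_signals(ps: ParcelSignals, cfg: RunConfig,
                  confounds: np.ndarray | pd.DataFrame | None = None
                  ) -> ParcelSignals:
    """Fixed-order cleaning: detrend/band-pass → nuisance regression → z-score."""
    logger.info("clean %s: detrend/bandpass %s -> %s regression -> zscore",
                ps.subject_id, cfg.bandpass,
                "nuisance" if confounds is not None else "no")
    out = bandpass_detrend(ps, *cfg.bandpass)
    if confounds is not None:
        out = regress_nuisance(out, confounds)
    return zscore(out)
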