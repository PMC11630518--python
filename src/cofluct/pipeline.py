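"""Per-subject metric extraction and the cohort-level stage runners.

This is the glue used by the command-line interface and the acceptance
checks: it chains cleaning → RSS dynamics → time-delay mapping →
inter-network FC per subject, isolates per-subject failures (a subject that
cannot be processed is excluded with a recorded reason, never aborting the
run), and hands the merged metric/phenotype table to the statistics stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from cofluct import edge_dynamics, fc, preprocess, stats, time_delay
from cofluct.io import (CohortTable, NetworkPartition, ParcelSignals,
                        RunConfig, UndefinedMetricError, ValidationError)
from cofluct.preprocess import MotionSummary
from cofluct.synthetic import CohortBundle

logger = logging.getLogger("cofluct")

__all__ = ["subject_metrics", "cohort_metrics", "run_stats"]


def subject_metrics(ps: ParcelSignals, part: NetworkPartition,
                    cfg: RunConfig,
                    confounds: np.ndarray | None = None,
                    clean: bool = True) -> dict:
    """All per-subject brain metrics as one flat row.

    Columns: mean_trough_duration (TR units by default), n_durations,
    mean_peak_height, n_peaks, td_smn (seconds), td_boundary_fraction,
    fc_static, fc_high, fc_low, n_pairs, n_frames_high, n_frames_low.
    """
    part.check_covers(ps)
    z = preprocess.clean_signals(ps, cfg, confounds) if clean else ps
    r = edge_dynamics.rss_from_signals(z)
    dur, n_dur = edge_dynamics.mean_trough_duration(r)
    if cfg.duration_units == "seconds":
        dur *= z.tr
    height, n_peaks = edge_dynamics.mean_peak_height(r)
    td_smn, boundary_frac = time_delay.network_td_from_signals(
        z, part, cfg.max_lag_tr, "SMN")
    summ = fc.internetwork_summary(z, r, part, cfg.amplitude_fraction,
                                   fisher_z=cfg.fisher_z)
    return {
        "subject_id": ps.subject_id,
        "mean_trough_duration": dur,
        "n_durations": n_dur,
        "mean_peak_height": height,
        "n_peaks": n_peaks,
        "td_smn": td_smn,
        "td_boundary_fraction": boundary_frac,
        "fc_static": summ.fc_static,
        "fc_high": summ.fc_high,
        "fc_low": summ.fc_low,
        "n_pairs": summ.n_pairs,
        "n_frames_high": summ.n_frames_high,
        "n_frames_low": summ.n_frames_low,
    }


def _motion_qc(row: pd.Series, cfg: RunConfig) -> preprocess.QCDecision:
    ms = MotionSummary(str(row.get("subject_id", "")), np.zeros(0),
                       float(row.get("mean_fd", 0.0)),
                       float(row.get("spike_fraction", 0.0)))
    return preprocess.motion_exclude(ms, cfg)


def cohort_metrics(bundle: CohortBundle, cfg: RunConfig,
                   clean: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metric rows for every motion-passing subject, plus a QC report.

    Returns ``(metrics, qc_report)``. Subjects excluded for motion or
    failing inside the metric chain appear only in the QC report with
    their reason.
    """
    rows, qc_rows = [], []
    for sub in bundle.subjects:
        sid = sub.signals.subject_id
        phen = bundle.phenotypes.df
        prow = phen.loc[phen.subject_id == sid].squeeze()
        decision = _motion_qc(prow, cfg) if len(prow) else \
            preprocess.QCDecision(True)
        if not decision.keep:
            qc_rows.append({"subject_id": sid, "decision": "exclude",
                            "reasons": "; ".join(decision.reasons)})
            continue
        try:
            rows.append(subject_metrics(sub.signals, bundle.partition, cfg,
                                        clean=clean))
        except (ValidationError, UndefinedMetricError) as err:
            logger.warning("subject %s excluded from metrics: %s", sid, err)
            qc_rows.append({"subject_id": sid, "decision": "exclude",
                            "reasons": str(err)})
            continue
        qc_rows.append({"subject_id": sid, "decision": "keep", "reasons": ""})
    return pd.DataFrame(rows), pd.DataFrame(qc_rows)


def run_stats(metrics: pd.DataFrame, phenotypes: CohortTable, cfg: RunConfig,
              include_controls: bool = True,
              include_itemwise: bool = True) -> dict[str, pd.DataFrame]:
    """Classify subjects, join metrics with phenotypes, run the full suite."""
    classified = stats.classify_subjects(phenotypes, cfg)
    keep = classified.df[classified.df.qc_pass]
    merged = keep.merge(metrics, on="subject_id", how="inner")
    unjoined = sorted(set(keep.subject_id) - set(merged.subject_id))
    if unjoined:
        logger.warning("subjects without metrics dropped from stats: %s",
                       unjoined[:10])
    return stats.run_full_contrast_suite(
        merged, cfg, include_controls=include_controls,
        include_itemwise=include_itemwise)
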