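"""Synthetic cohorts with known lag, event, coupling and phenotype structure.

The generator produces parcellated BOLD-like cohorts carrying exactly the
statistical structure the analysis pipeline assumes, with the ground truth
recorded alongside, so every stage can be scored against known answers
without any imaging data.

Signal model, per subject:

* band-limited Gaussian background sources (default 0.01–0.04 Hz, the slow
  portion of the analysis band, where resting BOLD carries most power): one
  brain-wide stationary source, one per-network source, one per parcel;
* a global event-gated source: Gaussian bumps (SD 1.2 TR) of random sign at
  the onsets of a Gamma renewal process. Events are the fastest substantial
  component, so RSS peaks sit on events and trough-to-trough durations
  track the inter-event interval;
* the event response is split into a brain-wide common part and
  network-private parts; together with the stationary source loadings this
  is solved so the expected SMN–DMN correlation matches
  ``smn_dmn_coupling`` (with an ``event_share`` split between event-borne
  and stationary covariance) while every other network pair sits at
  ``global_coupling`` — high-amplitude frames therefore carry more coupling
  than low-amplitude frames;
* the SMN's composite signal advanced by ``smn_lead`` seconds via an exact
  spectral (FFT phase) shift, so fractional lags are exact ground truth;
* white measurement noise on top.

Event structure, stationary background, and measurement noise come from
independent RNG substreams: regenerating a cohort with one aspect changed
(say, the event rate) leaves all other draws untouched, which makes paired
cohort comparisons sharp (common random numbers).

Default group structure mirrors the cohort under study: 44 agitated (A-MDD)
/ 75 non-agitated (NA-MDD) depressed patients and 94 healthy controls,
214 parcels, 240 frames at TR = 2 s; HAMD-17/HAMA phenotypes with item 9
(psychomotor agitation) driving the group label and totals truncated at the
inclusion minimum of 17 for patients, emulating the analyzed (post-
inclusion) sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cofluct.io import (CohortTable, HAMD_ITEM_MAX, NetworkPartition,
                        ParcelSignals, ValidationError, write_partition,
                        write_signals)

logger = logging.getLogger("cofluct")

__all__ = [
    "GroupSpec",
    "SyntheticSubject",
    "CohortBundle",
    "default_specs",
    "smoke_specs",
    "default_partition",
    "gen_event_train",
    "gen_subject_signals",
    "gen_phenotypes",
    "gen_cohort",
    "write_bundle",
    "read_bundle",
]

BAND = (0.01, 0.04)           # background-source band (lower part of 0.01-0.1 Hz)
EVENT_WIDTH_TR = 1.2          # Gaussian bump SD, frames


@dataclass
class GroupSpec:
    """Generative parameters for one group of subjects."""

    label: str
    n_subjects: int
    smn_lead: float = 0.0                   # seconds; positive = SMN leads
    inter_event_interval_mean: float = 13.0  # TR units
    inter_event_interval_shape: float = 3.0  # Gamma shape
    smn_dmn_coupling: float = 0.30           # target SMN-DMN Pearson r
    noise_sd: float = 0.15                   # relative to signal SD
    event_share: float = 0.40                # SMN-DMN coupling carried by events
    global_coupling: float = 0.40            # network-to-OTHER Pearson r target
    event_var: float = 0.50                  # per-parcel variance from events
    event_common: float = 0.50               # brain-wide fraction of event variance
    network_var: float = 0.08                # within-network coherent background
    event_width_tr: float = EVENT_WIDTH_TR   # Gaussian bump SD, frames
    source_band: tuple[float, float] = BAND  # background source band, Hz
    hamd_item9_distribution: tuple[float, ...] = (0.9, 0.1, 0.0, 0.0, 0.0)
    hamd_base: float = 3.0
    hamd_sd: float = 2.0
    hama_base: float = 3.0
    hama_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not -1 < self.smn_dmn_coupling < 1:
            raise ValidationError("coupling must lie in (-1, 1)")
        if self.inter_event_interval_mean <= 2:
            raise ValidationError("inter-event interval mean must exceed 2 TR")
        if abs(sum(self.hamd_item9_distribution) - 1.0) > 1e-9:
            raise ValidationError("item-9 distribution must sum to 1")


def default_specs() -> list[GroupSpec]:
    """The three study groups at the analyzed sample's size and structure.

    Effect directions follow the reported pattern: the agitated group has
    shorter inter-event intervals (faster state transitions), an earlier
    SMN lead relative to the non-agitated group, and reduced SMN–DMN
    coupling relative to controls. Magnitudes are chosen for detectability
    at these sample sizes, not to reproduce any particular statistic.
    """
    return [
        GroupSpec("A-MDD", 44, smn_lead=1.4, inter_event_interval_mean=7.0,
                  smn_dmn_coupling=0.06,
                  hamd_item9_distribution=(0.0, 0.0, 0.50, 0.35, 0.15),
                  hamd_base=30.8, hamd_sd=6.13, hama_base=24.8, hama_sd=7.17),
        GroupSpec("NA-MDD", 75, smn_lead=0.0, inter_event_interval_mean=13.0,
                  smn_dmn_coupling=0.25,
                  hamd_item9_distribution=(0.55, 0.45, 0.0, 0.0, 0.0),
                  hamd_base=25.2, hamd_sd=5.09, hama_base=19.7, hama_sd=6.22),
        GroupSpec("HC", 94, smn_lead=0.5, inter_event_interval_mean=13.0,
                  smn_dmn_coupling=0.38,
                  hamd_item9_distribution=(0.9, 0.1, 0.0, 0.0, 0.0),
                  hamd_base=3.0, hamd_sd=2.0, hama_base=3.0, hama_sd=2.0),
    ]


def smoke_specs(n_per_group: int = 5) -> list[GroupSpec]:
    """Same structure at reduced size for fast end-to-end runs."""
    specs = default_specs()
    for s in specs:
        s.n_subjects = n_per_group
    return specs


def default_partition(n_parcels: int) -> NetworkPartition:
    """SMN/DMN/OTHER split proportional to the 34/23/157-of-214 atlas."""
    if n_parcels < 6:
        raise ValidationError("need at least 6 parcels for a partition")
    n_smn = max(2, round(n_parcels * 34 / 214))
    n_dmn = max(2, round(n_parcels * 23 / 214))
    width = len(str(n_parcels))
    mapping = {}
    for k in range(n_parcels):
        pid = f"p{k + 1:0{width}d}"
        if k < n_smn:
            mapping[pid] = "SMN"
        elif k < n_smn + n_dmn:
            mapping[pid] = "DMN"
        else:
            mapping[pid] = "OTHER"
    return NetworkPartition(mapping)


@dataclass
class SyntheticSubject:
    signals: ParcelSignals
    truth: dict
    phenotype: dict = field(default_factory=dict)


@dataclass
class CohortBundle:
    subjects: list[SyntheticSubject]
    phenotypes: CohortTable
    partition: NetworkPartition
    truth: dict
    tr: float


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _bandlimited_noise(t: int, tr: float, rng: np.random.Generator,
                       low: float = BAND[0], high: float = BAND[1]
                       ) -> np.ndarray:
    """Unit-SD Gaussian noise with support restricted to [low, high] Hz."""
    freqs = np.fft.rfftfreq(t, d=tr)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ValidationError(
            f"band {low}-{high} Hz contains no Fourier bin at T={t}, TR={tr}")
    spec = np.zeros(freqs.size, dtype=complex)
    spec[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(
        mask.sum())
    x = np.fft.irfft(spec, n=t)
    return x / x.std()


def _spectral_shift(x: np.ndarray, shift_seconds: float, tr: float
                    ) -> np.ndarray:
    """Exact circular advance of ``x`` by ``shift_seconds`` (x(t + s))."""
    t = x.size
    freqs = np.fft.rfftfreq(t, d=tr)
    spec = np.fft.rfft(x) * np.exp(2j * np.pi * freqs * shift_seconds)
    return np.fft.irfft(spec, n=t)


def gen_event_train(t: int, interval_mean: float, shape: float,
                    rng: np.random.Generator | int) -> np.ndarray:
    """Event onsets (frames, float) from a Gamma renewal process on [0, T).

    Intervals are drawn by inverse CDF from one uniform each, so two trains
    generated from the same stream with different ``interval_mean`` are
    exact time-dilations of each other — paired cohorts differing only in
    event rate then share their event structure (common random numbers).
    """
    from scipy.stats import gamma as gamma_dist

    if interval_mean <= 2:
        raise ValidationError("interval mean must exceed 2 TR")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    scale = interval_mean / shape
    onsets = []
    pos = float(gamma_dist.ppf(rng.random(), shape) * scale)
    while pos < t:
        onsets.append(pos)
        pos += float(gamma_dist.ppf(rng.random(), shape) * scale)
    return np.asarray(onsets)


def _event_source(t: int, onsets: np.ndarray, rng: np.random.Generator,
                  width: float = EVENT_WIDTH_TR) -> np.ndarray:
    """Sum of random-sign Gaussian bumps at the event onsets, standardized."""
    if onsets.size == 0:
        return np.zeros(t)
    frames = np.arange(t)[:, None]
    # one uniform per event keeps sign sequences prefix-stable across
    # trains of different lengths drawn from the same stream
    signs = np.where(rng.random(onsets.size) < 0.5, -1.0, 1.0)
    g = (signs * np.exp(-((frames - onsets[None, :]) ** 2)
                        / (2.0 * width ** 2))).sum(axis=1)
    sd = g.std()
    if sd == 0:
        return np.zeros(t)
    return (g - g.mean()) / sd


def _solve_mixing(spec: GroupSpec) -> dict[str, float]:
    """Source loadings that realize the spec's correlation targets.

    Unit-variance budget per parcel (before measurement noise): stationary
    global source c with loading l, events with variance ``event_var`` (a
    brain-wide common response carrying an ``event_common`` fraction for
    SMN/OTHER, a DMN-specific fraction solved here), coherent within-network
    background ``network_var``, the remainder parcel-idiosyncratic. The DMN
    loadings are solved so the SMN-DMN correlation hits
    ``smn_dmn_coupling`` with an ``event_share`` split between event-borne
    and stationary covariance; every other network pair targets
    ``global_coupling``.
    """
    dil = 1.0 + spec.noise_sd ** 2
    rho_bg = spec.global_coupling * dil
    ev_bg = spec.event_var * spec.event_common
    if rho_bg <= ev_bg:
        raise ValidationError(
            f"global_coupling {spec.global_coupling} must exceed "
            f"{ev_bg / dil:.3f} (the common-event contribution)")
    l_base = np.sqrt(rho_bg - ev_bg)
    rho_sd = spec.smn_dmn_coupling * dil
    e = spec.event_share * rho_sd if rho_sd > 0 else 0.0
    s = rho_sd - e
    l_dmn = s / l_base
    q_dmn = (e / spec.event_var) ** 2 / spec.event_common
    if q_dmn > 1.0:
        bound = spec.event_var * np.sqrt(spec.event_common) / (
            spec.event_share * dil)
        raise ValidationError(
            f"coupling {spec.smn_dmn_coupling} infeasible: event-borne part "
            f"needs q > 1; |coupling| must be < {bound:.3f} at this "
            "event_share/event_var")
    for name, l in (("base", l_base), ("DMN", l_dmn)):
        if l ** 2 + spec.event_var + spec.network_var >= 1.0:
            bound = np.sqrt(1.0 - spec.event_var - spec.network_var)
            raise ValidationError(
                f"{name} stationary loading {l:.3f} exceeds the variance "
                f"budget; needs |l| < {bound:.3f}")
    return {"l_base": float(l_base), "l_dmn": float(l_dmn),
            "q_base": float(spec.event_common), "q_dmn": float(q_dmn)}


def gen_subject_signals(partition: NetworkPartition, t: int, tr: float,
                        spec: GroupSpec, seed: int | np.random.Generator,
                        subject_id: str = "synthetic") -> SyntheticSubject:
    """One subject's signals plus its ground-truth record.

    Raises if the requested coupling is infeasible for the configured noise
    and idiosyncratic-variance levels (the error reports the feasible bound).
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    parcel_ids = sorted(partition.mapping)
    networks = sorted(set(partition.mapping.values()))
    mix = _solve_mixing(spec)
    low, high = spec.source_band

    # Independent substreams: event structure, stationary background, and
    # measurement noise. Changing one generative aspect (e.g. the event
    # rate) then leaves every other draw untouched, so paired cohorts share
    # their background realizations (common random numbers).
    r_event, r_bg, r_noise = rng.spawn(3)

    onsets = gen_event_train(t, spec.inter_event_interval_mean,
                             spec.inter_event_interval_shape, r_event)
    common = _event_source(t, onsets, r_event, spec.event_width_tr)
    g_net = {}
    for net in networks:
        q = mix["q_dmn"] if net == "DMN" else mix["q_base"]
        private = _event_source(t, onsets, r_event, spec.event_width_tr)
        g_net[net] = np.sqrt(q) * common + np.sqrt(1.0 - q) * private

    c = _bandlimited_noise(t, tr, r_bg, low, high)
    gam = np.sqrt(spec.event_var)
    a_net = np.sqrt(spec.network_var)
    net_signal = {}
    for net in networks:
        l = mix["l_dmn"] if net == "DMN" else mix["l_base"]
        net_signal[net] = (l * c + gam * g_net[net]
                           + a_net * _bandlimited_noise(t, tr, r_bg, low, high))
    if "SMN" in net_signal and spec.smn_lead != 0.0:
        net_signal["SMN"] = _spectral_shift(net_signal["SMN"], spec.smn_lead,
                                            tr)

    data = np.empty((t, len(parcel_ids)))
    true_lags = {}
    for k, pid in enumerate(parcel_ids):
        net = partition.mapping[pid]
        l = mix["l_dmn"] if net == "DMN" else mix["l_base"]
        idio_var = 1.0 - l ** 2 - spec.event_var - spec.network_var
        base = net_signal[net] + np.sqrt(idio_var) * _bandlimited_noise(
            t, tr, r_bg, low, high)
        data[:, k] = base + spec.noise_sd * r_noise.standard_normal(t)
        true_lags[pid] = spec.smn_lead if net == "SMN" else 0.0

    signals = ParcelSignals(subject_id, data, parcel_ids, tr)
    truth = {
        "group": spec.label,
        "smn_lead_seconds": spec.smn_lead,
        "true_lags": true_lags,
        "event_onsets_frames": onsets.tolist(),
        "inter_event_interval_mean": spec.inter_event_interval_mean,
        "smn_dmn_coupling": spec.smn_dmn_coupling,
        "event_share": spec.event_share,
        "noise_sd": spec.noise_sd,
    }
    return SyntheticSubject(signals, truth)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

_REST_ITEMS = [i for i in HAMD_ITEM_MAX if i != 9]
_REST_MAX = sum(HAMD_ITEM_MAX[i] for i in _REST_ITEMS)  # 48


def _draw_hamd_items(target_total: float, item9: int,
                     rng: np.random.Generator) -> dict[int, int]:
    remaining = max(target_total - item9, 0.0)
    p = float(np.clip(remaining / _REST_MAX, 0.005, 0.995))
    items = {i: int(rng.binomial(HAMD_ITEM_MAX[i], p)) for i in _REST_ITEMS}
    items[9] = item9
    return items


def gen_phenotypes(specs: list[GroupSpec], rng: np.random.Generator | int,
                   inclusion_min: int = 17) -> CohortTable:
    """Group-structured phenotype rows for every subject in the specs.

    HAMD item 9 is drawn from each group's distribution; the remaining
    items are drawn to hit the group's total in expectation, and patient
    totals are raised to the inclusion minimum where needed (the generator
    emulates the post-inclusion analyzed sample). HAMA totals correlate
    with HAMD at about 0.5.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    rows = []
    for spec in specs:
        is_mdd = spec.label != "HC"
        for i in range(spec.n_subjects):
            sid = f"sub-{spec.label.replace('-', '').lower()}-{i + 1:03d}"
            item9 = int(rng.choice(5, p=spec.hamd_item9_distribution))
            target = rng.normal(spec.hamd_base, spec.hamd_sd)
            if is_mdd:
                target = max(target, float(inclusion_min))
            items = _draw_hamd_items(target, item9, rng)
            total = sum(items.values())
            if is_mdd:
                while total < inclusion_min:
                    j = int(rng.choice(_REST_ITEMS))
                    if items[j] < HAMD_ITEM_MAX[j]:
                        items[j] += 1
                        total += 1
            hama = (spec.hama_base
                    + 0.5 * (spec.hama_sd / max(spec.hamd_sd, 1e-9))
                    * (total - spec.hamd_base)
                    + spec.hama_sd * np.sqrt(0.75) * rng.standard_normal())
            row = {
                "subject_id": sid,
                "cohort": "MDD" if is_mdd else "HC",
                "true_group": spec.label,
                "age": float(np.clip(round(rng.normal(34, 12)), 18, 70)),
                "gender": str(rng.choice(
                    ["female", "male"],
                    p=[0.76, 0.24] if is_mdd else [0.35, 0.65])),
                "education": int(rng.choice(
                    6, p=[0.01, 0.05, 0.12, 0.20, 0.45, 0.17])),
                "hamd_total": int(total),
                "hama_total": int(np.clip(round(hama), 0, 56)),
                "mean_fd": float(np.clip(rng.normal(0.12, 0.05), 0.01, 0.24)),
                "spike_fraction": float(rng.uniform(0.0, 0.10)),
            }
            for j in range(1, 18):
                row[f"hamd_{j:02d}"] = items[j]
            rows.append(row)
    return CohortTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohort assembly and bundle I/O
# ---------------------------------------------------------------------------

def gen_cohort(specs: list[GroupSpec], n_parcels: int = 214, t: int = 240,
               tr: float = 2.0, seed: int = 0,
               partition: NetworkPartition | None = None) -> CohortBundle:
    """A full cohort: signals + phenotypes + ground-truth manifest.

    Per-subject seeds are spawned deterministically from the master seed,
    so the same seed reproduces the bundle byte-for-byte.
    """
    labels = [s.label for s in specs]
    if len(labels) != len(set(labels)):
        raise ValidationError("group labels must be unique")
    part = partition or default_partition(n_parcels)
    ss = np.random.SeedSequence(seed)
    n_total = sum(s.n_subjects for s in specs)
    children = ss.spawn(n_total + 1)
    phenotypes = gen_phenotypes(specs, np.random.default_rng(children[0]))

    subjects: list[SyntheticSubject] = []
    k = 0
    for spec in specs:
        for _ in range(spec.n_subjects):
            sid = phenotypes.df.iloc[len(subjects)]["subject_id"]
            sub = gen_subject_signals(part, t, tr, spec,
                                      np.random.default_rng(children[k + 1]),
                                      subject_id=sid)
            sub.phenotype = phenotypes.df.iloc[len(subjects)].to_dict()
            subjects.append(sub)
            k += 1
    truth = {
        "seed": seed,
        "tr": tr,
        "n_frames": t,
        "n_parcels": len(part.mapping),
        "groups": {s.label: {
            "n_subjects": s.n_subjects,
            "smn_lead_seconds": s.smn_lead,
            "inter_event_interval_mean": s.inter_event_interval_mean,
            "smn_dmn_coupling": s.smn_dmn_coupling,
            "noise_sd": s.noise_sd,
        } for s in specs},
        "subjects": {sub.signals.subject_id: sub.truth for sub in subjects},
    }
    return CohortBundle(subjects, phenotypes, part, truth, tr)


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "signals").mkdir(parents=True, exist_ok=True)
    for sub in bundle.subjects:
        write_signals(sub.signals, out / "signals" / f"{sub.signals.subject_id}.tsv")
    bundle.phenotypes.df.to_csv(out / "phenotypes.csv", index=False,
                                float_format="%.17g", lineterminator="\n")
    write_partition(bundle.partition, out / "partition.tsv")
    (out / "truth.json").write_text(
        json.dumps(bundle.truth, indent=2, sort_keys=True) + "\n")


def read_bundle(in_dir: str | Path, tr: float | None = None) -> CohortBundle:
    from cofluct.io import read_partition, read_phenotypes, read_signals

    src = Path(in_dir)
    truth = json.loads((src / "truth.json").read_text())
    tr = tr if tr is not None else float(truth["tr"])
    part = read_partition(src / "partition.tsv")
    phen = read_phenotypes(src / "phenotypes.csv")
    subjects = []
    for sid in phen.df["subject_id"]:
        ps = read_signals(src / "signals" / f"{sid}.tsv", tr, subject_id=sid)
        subjects.append(SyntheticSubject(ps, truth["subjects"].get(sid, {})))
    return CohortBundle(subjects, phen, part, truth, tr)
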