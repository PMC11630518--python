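"""Tabular I/O, run configuration, and the core data containers.

Every other stage of the pipeline talks through the types defined here:

* :class:`ParcelSignals` — one subject's time × parcel BOLD matrix with its
  repetition time (TR).
* :class:`NetworkPartition` — parcel → network assignment (SMN, DMN, OTHER).
* :class:`CohortTable` — per-subject phenotypes (HAMD-17 items, HAMA, age,
  gender, education, motion summaries) plus QC flags and group labels.
* :class:`RunConfig` — every tunable threshold of the analysis, sourced from
  one structured config file so a run is fully described by (inputs, config,
  seed).

Signals are stored on disk as UTF-8 TSV with a header row of parcel IDs and
one row per frame; partitions as two-column TSV; phenotypes as CSV. Writers
are deterministic: identical inputs reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cofluct")

__all__ = [
    "FormatError",
    "ValidationError",
    "UndefinedMetricError",
    "ParcelSignals",
    "NetworkPartition",
    "CohortTable",
    "RunConfig",
    "HAMD_ITEM_MAX",
    "read_signals",
    "write_signals",
    "read_partition",
    "write_partition",
    "read_phenotypes",
    "write_results",
]


class FormatError(ValueError):
    """A file does not conform to the documented on-disk contract."""


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


class UndefinedMetricError(RuntimeError):
    """A metric is undefined for this input (e.g. fewer than two troughs)."""


#: Maximum score per HAMD-17 item. Items 1-3, 7-11 and 15 are rated 0-4;
#: the somatic/insomnia items are rated 0-2. Item 9 is psychomotor agitation.
HAMD_ITEM_MAX = {
    1: 4, 2: 4, 3: 4, 4: 2, 5: 2, 6: 2, 7: 4, 8: 4, 9: 4,
    10: 4, 11: 4, 12: 2, 13: 2, 14: 2, 15: 4, 16: 2, 17: 2,
}

KNOWN_NETWORKS = ("SMN", "DMN", "OTHER")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ParcelSignals:
    """One subject's parcellated BOLD time series.

    ``data`` has rows = time frames and columns = parcels, aligned with
    ``parcel_ids``. ``tr`` is the repetition time in seconds.
    """

    subject_id: str
    data: np.ndarray
    parcel_ids: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.parcel_ids = [str(p) for p in self.parcel_ids]
        if self.data.ndim != 2:
            raise ValidationError("signal data must be a 2-D time × parcel matrix")
        t, n = self.data.shape
        if n < 2:
            raise ValidationError(f"need at least 2 parcels, got {n}")
        if t < 10:
            raise ValidationError(f"need at least 10 frames, got {t}")
        if len(self.parcel_ids) != n:
            raise ValidationError(
                f"{len(self.parcel_ids)} parcel IDs for {n} columns")
        if len(set(self.parcel_ids)) != n:
            raise ValidationError("parcel IDs must be unique")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValidationError(
                f"non-finite value at frame {bad[0]}, parcel "
                f"{self.parcel_ids[bad[1]]}")
        if not self.tr > 0:
            raise ValidationError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ParcelSignals":
        """Copy carrying new values but the same identity/metadata."""
        return ParcelSignals(self.subject_id, data, list(self.parcel_ids), self.tr)


@dataclass
class NetworkPartition:
    """Parcel → network label mapping (labels upper-case, e.g. SMN, DMN, OTHER)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v).upper() for k, v in self.mapping.items()}

    def label_of(self, parcel_id: str) -> str:
        return self.mapping[parcel_id]

    def parcels(self, label: str) -> list[str]:
        label = label.upper()
        return [p for p, lab in self.mapping.items() if lab == label]

    def labels(self) -> set[str]:
        return set(self.mapping.values())

    def check_covers(self, ps: ParcelSignals) -> None:
        missing = [p for p in ps.parcel_ids if p not in self.mapping]
        if missing:
            raise ValidationError(
                f"partition missing labels for parcels: {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))


HAMD_COLS = [f"hamd_{i:02d}" for i in range(1, 18)]


@dataclass
class CohortTable:
    """Per-subject phenotype table.

    Expected columns: ``subject_id`` (required) and optionally ``age``,
    ``gender``, ``education``, ``hamd_01``..``hamd_17``, ``hamd_total``,
    ``hama_total``, ``mean_fd``, ``spike_fraction``, ``cohort`` (MDD/HC),
    ``group_label``, ``qc_pass``. Missing optional values stay missing and
    are dropped listwise only inside individual statistical models.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if "subject_id" not in df.columns:
            raise ValidationError("phenotype table needs a subject_id column")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        for item, cap in HAMD_ITEM_MAX.items():
            col = f"hamd_{item:02d}"
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                bad = df.loc[vals.notna() & ((vals < 0) | (vals > cap)), "subject_id"]
                if len(bad):
                    raise ValidationError(
                        f"{col} outside 0..{cap} for subjects: {list(bad)}")
        if "age" in df.columns:
            age = pd.to_numeric(df["age"], errors="coerce")
            bad = df.loc[age.notna() & (age < 0), "subject_id"]
            if len(bad):
                raise ValidationError(f"negative age for subjects: {list(bad)}")
        present_items = [c for c in HAMD_COLS if c in df.columns]
        if len(present_items) == 17 and "hamd_total" in df.columns:
            items = df[present_items].apply(pd.to_numeric, errors="coerce")
            total = pd.to_numeric(df["hamd_total"], errors="coerce")
            full = items.notna().all(axis=1) & total.notna()
            mismatch = df.loc[full & (items.sum(axis=1) != total), "subject_id"]
            if len(mismatch):
                raise ValidationError(
                    f"hamd_total != sum of items for subjects: {list(mismatch)}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RunConfig:
    """All tunable parameters of a run.

    Defaults follow the analysis conditions: TR-2 s acquisitions band-passed
    at 0.01-0.1 Hz, motion exclusion at mean FD > 0.25 mm or > 25% spike
    frames (spike = frame with FD > 0.25 mm), agitation cutoff HAMD item 9
    >= 2, depression inclusion HAMD-17 >= 17, amplitude conditioning on the
    top/bottom 10% of RSS frames, and a lag-search window of +/- 3 TR.
    """

    max_lag_tr: int = 3
    amplitude_fraction: float = 0.10
    bandpass: tuple[float, float] = (0.01, 0.10)
    fd_mean_threshold: float = 0.25
    fd_spike_threshold: float = 0.25
    fd_spike_fraction: float = 0.25
    agitation_cutoff: int = 2
    hamd_inclusion_min: int = 17
    seed: int = 0
    # depression "sub-dimension" covariate: HAMD items used (never item 9)
    depression_subdim_items: tuple[int, ...] = (1, 2, 3, 7)
    fisher_z: bool = False            # average FC on Fisher-z scale instead of raw r
    amplitude_on_extrema: bool = False  # restrict top/bottom selection to peak/trough frames
    duration_units: str = "tr"        # or "seconds"

    def __post_init__(self) -> None:
        low, high = self.bandpass
        if not (0 < low < high):
            raise ValidationError("bandpass must satisfy 0 < low < high")
        if not (0 < self.amplitude_fraction < 0.5):
            raise ValidationError("amplitude_fraction must lie in (0, 0.5)")
        if self.max_lag_tr < 1:
            raise ValidationError("max_lag_tr must be >= 1")
        if 9 in self.depression_subdim_items:
            raise ValidationError(
                "depression sub-dimension must not include HAMD item 9")

    def check_band(self, tr: float) -> None:
        nyq = 1.0 / (2.0 * tr)
        if not self.bandpass[1] < nyq:
            raise ValidationError(
                f"bandpass high {self.bandpass[1]} Hz >= Nyquist {nyq} Hz for TR {tr}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bandpass"] = list(d["bandpass"])
        d["depression_subdim_items"] = list(d["depression_subdim_items"])
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "bandpass" in kwargs:
            kwargs["bandpass"] = tuple(kwargs["bandpass"])
        if "depression_subdim_items" in kwargs:
            kwargs["depression_subdim_items"] = tuple(kwargs["depression_subdim_items"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_signals(path: str | Path, tr: float, transpose: bool = False,
                 subject_id: str | None = None) -> ParcelSignals:
    """Read a time × parcel signal table (TSV/CSV, header = parcel IDs).

    With ``transpose=True`` the file is parcels × frames with the parcel ID
    in the first column; nothing is ever auto-detected.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().strip("\n\r")
    if not header_line:
        raise FormatError(f"{path.name}: empty file")
    if transpose:
        body = pd.read_csv(path, sep=sep, index_col=0,
                           float_precision="round_trip")
        parcel_ids = [str(p) for p in body.index]
        if len(parcel_ids) != len(set(parcel_ids)):
            dup = next(p for p in parcel_ids if parcel_ids.count(p) > 1)
            raise FormatError(f"{path.name}: duplicated parcel ID {dup!r}")
        n_frames = body.shape[1]
    else:
        header = header_line.split(sep)
        if len(header) != len(set(header)):
            dup = next(h for h in header if header.count(h) > 1)
            raise FormatError(f"{path.name}: duplicated parcel ID {dup!r}")
        body = pd.read_csv(path, sep=sep, float_precision="round_trip")
        parcel_ids = [str(c) for c in body.columns]
        n_frames = body.shape[0]
    if len(parcel_ids) < 2:
        raise FormatError(f"{path.name}: fewer than 2 parcel columns")
    if n_frames == 0:
        raise FormatError(f"{path.name}: no frames (header only)")
    numeric = body.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        arr = numeric.to_numpy()
        r, c = np.argwhere(np.isnan(arr))[0]
        raise FormatError(
            f"{path.name}: non-numeric cell at row {r + 1}, column "
            f"{body.columns[c]!r}")
    if subject_id is None:
        subject_id = path.stem
    values = numeric.to_numpy().T if transpose else numeric.to_numpy()
    return ParcelSignals(subject_id, values, parcel_ids, tr)


def write_signals(ps: ParcelSignals, path: str | Path) -> None:
    df = pd.DataFrame(ps.data, columns=ps.parcel_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")


def read_partition(path: str | Path) -> NetworkPartition:
    """Read a two-column parcel_id / network_label table.

    Labels are upper-cased; labels outside {SMN, DMN, OTHER} are remapped to
    OTHER with a warning. Duplicate parcel IDs are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path.name}: expected columns parcel_id, network_label")
    ids = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1].astype(str).str.upper()
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"{path.name}: duplicate parcel_id {dup!r}")
    unknown = sorted(set(labels) - set(KNOWN_NETWORKS))
    if unknown:
        logger.warning("partition %s: unknown labels %s mapped to OTHER",
                       path.name, unknown)
        labels = labels.where(labels.isin(KNOWN_NETWORKS), "OTHER")
    return NetworkPartition(dict(zip(ids, labels)))


def write_partition(part: NetworkPartition, path: str | Path) -> None:
    df = pd.DataFrame(sorted(part.mapping.items()),
                      columns=["parcel_id", "network_label"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_phenotypes(path: str | Path,
                    column_map: Mapping[str, str] | None = None) -> CohortTable:
    """Read the per-subject phenotype CSV.

    ``column_map`` renames source columns to the documented names
    (e.g. ``{"HAMD9": "hamd_09"}``) so deposited tables with other headers
    can be ingested without editing files.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing_opt = [c for c in ("age", "gender", "education") if
                   c in df.columns and df[c].isna().any()]
    if missing_opt:
        logger.warning("phenotypes %s: missing values in %s (retained)",
                       path.name, missing_opt)
    return CohortTable(df)


# ---------------------------------------------------------------------------
# result writer
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  config: RunConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write one TSV per result family plus a JSON manifest.

    The manifest records a config hash, the seed, and a checksum per file;
    re-running with identical inputs reproduces byte-identical TSVs.
    """
    from cofluct import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        if len(df) == 0:
            logger.warning("result table %s is empty (header-only TSV written)", name)
        df.to_csv(p, sep="\t", index=False, float_format="%.17g",
                  lineterminator="\n")
        files[name] = _sha256(p)
    cfg_dict = config.to_dict() if config is not None else None
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "files": files,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
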