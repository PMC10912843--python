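"""Reading, writing and conditioning of ROI time-series cohorts.

The pipeline operates on per-subject matrices of parcellated BOLD signal,
``n_regions x n_timepoints`` (regions as rows), sampled every ``tr_seconds``
seconds, together with a subject metadata table (group label, age, sex,
education, MoCA score).  This module provides the on-disk round trip
(one delimited matrix file per subject + one metadata table), optional ROI
extraction from labelled volumes, and the two pre-model conditioning steps:
zero-phase band-pass filtering and per-region z-scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "ROITimeSeries",
    "SubjectMeta",
    "Cohort",
    "load_cohort",
    "save_cohort",
    "extract_roi_timeseries",
    "bandpass_filter",
    "standardize",
]


@dataclass
class ROITimeSeries:
    """One subject's parcellated BOLD matrix.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    data : ndarray, shape (n_regions, n_timepoints)
        BOLD amplitude in arbitrary units, regions as rows.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    region_labels : list of str
        One unique label per region (atlas names or generic ``R001``...).
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: data must be 2-D, got {self.data.ndim}-D")
        n_regions, n_timepoints = self.data.shape
        if n_regions < 2 or n_timepoints < 2:
            raise ValueError(
                f"{self.subject_id}: need >= 2 regions and >= 2 timepoints, "
                f"got {n_regions} x {n_timepoints}"
            )
        if self.tr_seconds <= 0:
            raise ValueError(f"{self.subject_id}: tr_seconds must be positive")
        if not self.region_labels:
            self.region_labels = [f"R{i + 1:03d}" for i in range(n_regions)]
        if len(self.region_labels) != n_regions:
            raise ValueError(
                f"{self.subject_id}: {len(self.region_labels)} labels for {n_regions} regions"
            )
        if len(set(self.region_labels)) != n_regions:
            raise ValueError(f"{self.subject_id}: region labels are not unique")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectMeta:
    """Demographic / clinical record for one subject.

    ``group`` is the diagnostic label (e.g. ``patient`` / ``control``).
    ``moca`` is the Montreal Cognitive Assessment total (0-30); subjects
    scoring below 26 are conventionally classed as cognitively impaired.
    """

    subject_id: str
    group: str
    age: float = np.nan
    sex: str = ""
    education: float = np.nan
    moca: float | None = None

    def __post_init__(self) -> None:
        if self.moca is not None and not np.isnan(self.moca):
            if not 0 <= self.moca <= 30:
                raise ValueError(
                    f"{self.subject_id}: MoCA score {self.moca} outside [0, 30]"
                )


@dataclass
class Cohort:
    """Aligned lists of time series and metadata for a study sample."""

    series: list[ROITimeSeries]
    meta: list[SubjectMeta]

    def __post_init__(self) -> None:
        if len(self.series) != len(self.meta):
            raise ValueError(
                f"{len(self.series)} series but {len(self.meta)} metadata rows"
            )
        ids_s = [ts.subject_id for ts in self.series]
        ids_m = [m.subject_id for m in self.meta]
        if ids_s != ids_m:
            raise ValueError("series and metadata subject_id order mismatch")
        if len(set(ids_s)) != len(ids_s):
            raise ValueError("duplicate subject_id in cohort")
        if self.series:
            ref = self.series[0]
            for ts in self.series[1:]:
                if ts.n_regions != ref.n_regions:
                    raise ValueError(
                        f"region count mismatch: {ts.subject_id} has {ts.n_regions}, "
                        f"{ref.subject_id} has {ref.n_regions}"
                    )
                if ts.region_labels != ref.region_labels:
                    raise ValueError(f"region labels of {ts.subject_id} differ from {ref.subject_id}")
                if ts.tr_seconds != ref.tr_seconds:
                    raise ValueError(f"TR mismatch for {ts.subject_id}")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def subject_ids(self) -> list[str]:
        return [ts.subject_id for ts in self.series]

    @property
    def n_regions(self) -> int:
        return self.series[0].n_regions

    @property
    def region_labels(self) -> list[str]:
        return self.series[0].region_labels

    @property
    def tr_seconds(self) -> float:
        return self.series[0].tr_seconds

    def subset(self, subject_ids: Sequence[str]) -> "Cohort":
        keep = set(subject_ids)
        idx = [i for i, s in enumerate(self.subject_ids) if s in keep]
        return Cohort([self.series[i] for i in idx], [self.meta[i] for i in idx])

    def groups(self) -> dict[str, list[str]]:
        """Map group label -> subject ids, in cohort order."""
        out: dict[str, list[str]] = {}
        for m in self.meta:
            out.setdefault(m.group, []).append(m.subject_id)
        return out


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

_META_COLUMNS = ["subject_id", "group", "age", "sex", "education", "moca"]


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str]]:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    orient_label = str(df.index.name or "").strip().lower()
    if orient_label.startswith("timepoint") or orient_label in ("t", "time"):
        df = df.T
        logger.warning("%s: rows flagged as timepoints; transposing to regions x timepoints", path.name)
    try:
        data = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i, row in enumerate(df.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path.name}: non-numeric cell at row {i + 1}, column {j + 1}: {v!r}"
                    ) from None
        raise
    if not np.isfinite(data).all():
        i, j = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(
            f"{path.name}: non-finite value at row {int(i) + 1}, column {int(j) + 1}"
        )
    labels = [str(x) for x in df.index]
    return data, labels


def load_cohort(matrix_dir: str | Path, meta_table: str | Path, tr_seconds: float = 2.0,
                drop_initial_volumes: int = 0) -> Cohort:
    """Load one matrix file per subject plus a metadata table.

    Subjects present in only one of the two sources are dropped with a
    logged warning; mismatched region counts or non-numeric cells are hard
    errors naming the offending file and position.

    Parameters
    ----------
    matrix_dir : path
        Directory of ``<subject_id>.tsv``/``.csv`` matrices
        (regions x timepoints, first column region labels).
    meta_table : path
        Delimited table with columns subject_id, group, age, sex,
        education, moca.
    tr_seconds : float
        Sampling interval of the series (the files carry no TR).
    drop_initial_volumes : int
        Leading volumes to discard from every matrix (for raw exports
        where scanner-settling volumes were not already removed).
    """
    matrix_dir = Path(matrix_dir)
    meta_path = Path(meta_table)
    sep = "," if meta_path.suffix.lower() == ".csv" else "\t"
    meta_df = pd.read_csv(meta_path, sep=sep)
    missing = [c for c in ("subject_id", "group") if c not in meta_df.columns]
    if missing:
        raise ValueError(f"{meta_path.name}: missing required columns {missing}")

    files = {p.stem: p for p in sorted(matrix_dir.iterdir())
             if p.suffix.lower() in (".tsv", ".csv")}
    meta_ids = [str(s) for s in meta_df["subject_id"]]
    common = [s for s in meta_ids if s in files]
    orphans = sorted(set(files) ^ set(meta_ids))
    if orphans:
        logger.warning("dropping subjects present in only one source: %s", ", ".join(orphans))

    series: list[ROITimeSeries] = []
    meta: list[SubjectMeta] = []
    shapes: dict[int, str] = {}
    for sid in common:
        data, labels = _read_matrix(files[sid])
        if drop_initial_volumes:
            data = data[:, drop_initial_volumes:]
        ts = ROITimeSeries(sid, data, tr_seconds, labels)
        shapes.setdefault(ts.n_regions, files[sid].name)
        if len(shapes) > 1:
            detail = "; ".join(f"{n} regions in {f}" for n, f in shapes.items())
            raise ValueError(f"mismatched region counts across subjects: {detail}")
        row = meta_df.loc[meta_df["subject_id"].astype(str) == sid].iloc[0]
        moca = row.get("moca", np.nan)
        meta.append(SubjectMeta(
            subject_id=sid,
            group=str(row["group"]),
            age=float(row.get("age", np.nan)),
            sex=str(row.get("sex", "")),
            education=float(row.get("education", np.nan)),
            moca=None if pd.isna(moca) else float(moca),
        ))
        series.append(ts)
    return Cohort(series, meta)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a cohort as TSV matrices plus ``meta.tsv``; returns the paths.

    Floats are written with 17 significant digits so that
    load -> save -> load round-trips bit-identically.
    """
    out_dir = Path(out_dir)
    matrices = out_dir / "matrices"
    matrices.mkdir(parents=True, exist_ok=True)
    for ts in cohort.series:
        df = pd.DataFrame(ts.data, index=pd.Index(ts.region_labels, name="region"),
                          columns=[f"t{j}" for j in range(ts.n_timepoints)])
        df.to_csv(matrices / f"{ts.subject_id}.tsv", sep="\t", float_format="%.17g")
    rows = [{
        "subject_id": m.subject_id, "group": m.group, "age": m.age,
        "sex": m.sex, "education": m.education,
        "moca": np.nan if m.moca is None else m.moca,
    } for m in cohort.meta]
    meta_path = out_dir / "meta.tsv"
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(meta_path, sep="\t", index=False)
    return matrices, meta_path


# ---------------------------------------------------------------------------
# ROI extraction from labelled volumes
# ---------------------------------------------------------------------------

def extract_roi_timeseries(volume_4d: np.ndarray, label_volume: np.ndarray,
                           label_names: Mapping[int, str], tr_seconds: float = 2.0,
                           subject_id: str = "subject") -> ROITimeSeries:
    """Average the 4-D signal over voxels of each labelled ROI.

    Row ``r`` of the output is the mean over voxels carrying the r-th label
    (sorted label order) at each timepoint; label 0 is background.  Labels
    with no voxels produce an all-NaN row and a warning.
    """
    volume_4d = np.asarray(volume_4d, dtype=float)
    label_volume = np.asarray(label_volume)
    if volume_4d.shape[:3] != label_volume.shape:
        raise ValueError(
            f"spatial shape mismatch: volume {volume_4d.shape[:3]} vs labels {label_volume.shape}"
        )
    labels = sorted(k for k in label_names if k != 0)
    n_t = volume_4d.shape[3]
    data = np.full((len(labels), n_t), np.nan)
    flat = volume_4d.reshape(-1, n_t)
    lab_flat = label_volume.reshape(-1)
    for r, lab in enumerate(labels):
        mask = lab_flat == lab
        if not mask.any():
            warnings.warn(f"label {lab} ({label_names[lab]}) has no voxels; NaN row emitted")
            continue
        data[r] = flat[mask].mean(axis=0)
    return ROITimeSeries(subject_id, data, tr_seconds, [label_names[lab] for lab in labels])


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def bandpass_filter(ts: ROITimeSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> ROITimeSeries:
    """Zero-phase band-pass each region's time course.

    An order-4 Butterworth design applied forward and backward
    (``sosfiltfilt``), so state timing is not shifted.  ``low_hz = 0``
    degenerates to a low-pass.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} Hz is at or above the Nyquist frequency "
            f"{nyquist} Hz for TR={ts.tr_seconds} s"
        )
    fs = 1.0 / ts.tr_seconds
    if low_hz > 0:
        sos = signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    else:
        sos = signal.butter(2, high_hz, btype="lowpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return replace(ts, data=filtered)


def standardize(ts: ROITimeSeries) -> ROITimeSeries:
    """Z-score each region's time course (mean 0, sample SD 1, ddof=1).

    Idempotent; a zero-variance region is a hard error naming the region.
    """
    mean = ts.data.mean(axis=1, keepdims=True)
    sd = ts.data.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        names = ", ".join(ts.region_labels[i] for i in bad[:5])
        raise ValueError(f"{ts.subject_id}: zero-variance region(s): {names}")
    return replace(ts, data=(ts.data - mean) / sd)
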