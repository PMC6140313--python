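"""Reading, validating and writing velocity-track exports and subject metadata.

The canonical tracking export is long-format delimited text with one row per
subject x time sample (columns ``subject_id, time_s, velocity_mm_s``), the
format every mainstream video tracker can produce. A missing velocity (the
animal was not detected in that frame sample) is an empty field, never zero:
zero is a legitimate observation meaning "immobile", missing means "unknown".
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACKING_COLUMNS = ("subject_id", "time_s", "velocity_mm_s")
RESULTS_COLUMNS = (
    "subject_id",
    "treatment",
    "body_size_mm",
    "timm_s",
    "censored",
    "n_missing",
    "v_thresh",
    "w",
)


@dataclass(frozen=True)
class TrackingDialect:
    """How to parse a tracking export.

    ``sample_rate`` is an optional expected rate (obs/s); when given, every
    observed time stamp must sit on the implied grid to within
    ``rate_tolerance`` of a step, otherwise the file is rejected — this
    catches mixed-rate exports early. Without it, the grid step is inferred
    per subject from the time stamps.
    """

    delimiter: str = ","
    na_values: tuple[str, ...] = ("",)
    sample_rate: float | None = None
    rate_tolerance: float = 0.01


@dataclass
class VelocityTrack:
    """One individual's uniformly sampled swimming-velocity series.

    ``velocities`` is a float array in mm/s with NaN marking samples where the
    subject was not detected. Sample ``i`` was recorded at ``i / sample_rate``
    seconds after recording start; ``intro_offset_s`` is the time the animal
    had already spent in its well when recording started.
    """

    subject_id: str
    sample_rate: float
    velocities: np.ndarray
    intro_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.ndim != 1 or self.velocities.size == 0:
            raise ValueError(
                f"subject {self.subject_id!r}: velocities must be a non-empty 1-d sequence"
            )
        if not self.sample_rate > 0:
            raise ValueError(f"subject {self.subject_id!r}: sample_rate must be > 0")
        if self.intro_offset_s < 0:
            raise ValueError(f"subject {self.subject_id!r}: intro_offset_s must be >= 0")
        present = self.velocities[~np.isnan(self.velocities)]
        if (present < 0).any():
            raise ValueError(f"subject {self.subject_id!r}: negative velocity values")

    @property
    def n_samples(self) -> int:
        return int(self.velocities.size)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.velocities).sum())

    @property
    def times_s(self) -> np.ndarray:
        """Elapsed time of each sample from recording start."""
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class SubjectMeta:
    """Per-individual covariates: treatment label, body size, design labels."""

    subject_id: str
    treatment: str
    body_size_mm: float = float("nan")
    intro_offset_s: float = 0.0
    block: str = ""
    run: str = ""

    def __post_init__(self) -> None:
        if not np.isnan(self.body_size_mm) and not self.body_size_mm > 0:
            raise ValueError(
                f"subject {self.subject_id!r}: body_size_mm must be > 0 when present"
            )
        if self.intro_offset_s < 0:
            raise ValueError(f"subject {self.subject_id!r}: intro_offset_s must be >= 0")


@dataclass
class Dataset:
    """Tracks joined one-to-one with metadata on subject_id."""

    tracks: list[VelocityTrack]
    meta: list[SubjectMeta]
    orphan_track_ids: tuple[str, ...] = ()
    orphan_meta_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        track_ids = [t.subject_id for t in self.tracks]
        meta_ids = [m.subject_id for m in self.meta]
        if track_ids != meta_ids:
            raise ValueError("tracks and meta must be aligned one-to-one on subject_id")

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def subject_ids(self) -> list[str]:
        return [t.subject_id for t in self.tracks]

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame indexed by subject_id."""
        df = pd.DataFrame(
            {
                "treatment": [m.treatment for m in self.meta],
                "body_size_mm": [m.body_size_mm for m in self.meta],
                "intro_offset_s": [m.intro_offset_s for m in self.meta],
                "block": [m.block for m in self.meta],
                "run": [m.run for m in self.meta],
            },
            index=pd.Index(self.subject_ids, name="subject_id"),
        )
        return df


def _float_gcd(values: np.ndarray, rel_tol: float = 1e-3) -> float:
    """Approximate greatest common divisor of positive floats (Euclid)."""
    g = float(values[0])
    for v in values[1:]:
        a, b = max(g, float(v)), min(g, float(v))
        while b > rel_tol * a:
            a, b = b, a - np.floor(a / b) * b
        g = a
    return g


def _reconstruct_grid(
    subject_id: str, times: np.ndarray, velocities: np.ndarray, dialect: TrackingDialect
) -> VelocityTrack:
    """Place observed rows on a uniform time grid, filling gaps with NaN.

    The grid is anchored at the subject's first observed time. With a
    configured rate, every observed interval must sit on that grid (an
    integer number of steps, within tolerance) — this rejects mixed-rate
    files early. Without one, the step is inferred as the approximate GCD of
    the inter-sample intervals, which recovers the grid even when dropped
    frames make gaps more common than single steps.
    """
    diffs = np.diff(times)
    if diffs.min(initial=np.inf) <= 0:
        raise ValueError(f"subject {subject_id!r}: time_s not strictly increasing")
    if dialect.sample_rate is not None:
        rate = dialect.sample_rate
        if times.size > 1:
            steps = diffs * rate
            off_grid = np.abs(steps - np.rint(steps)).max()
            if off_grid > dialect.rate_tolerance or (np.rint(steps) < 1).any():
                raise ValueError(
                    f"subject {subject_id!r}: observed time steps are not "
                    f"multiples of 1/{rate:g} s (off-grid by up to "
                    f"{off_grid:.3f} steps > {dialect.rate_tolerance:g} tolerance); "
                    f"configured sample rate inconsistent with the data"
                )
    else:
        if times.size == 1:
            raise ValueError(
                f"subject {subject_id!r}: cannot infer sample rate from a single row"
            )
        dt = _float_gcd(diffs)
        if dt < diffs.min() / 1000:
            # jittered, not gridded: fall back to the typical interval
            dt = float(np.percentile(diffs, 50, method="lower"))
        rate = 1.0 / dt
    idx = np.rint((times - times[0]) * rate).astype(int)
    if np.unique(idx).size != idx.size:
        raise ValueError(
            f"subject {subject_id!r}: rows collide on the uniform time grid "
            f"(irregular sampling beyond tolerance)"
        )
    grid = np.full(int(idx[-1]) + 1, np.nan)
    grid[idx] = velocities
    return VelocityTrack(subject_id=subject_id, sample_rate=float(rate), velocities=grid)


def read_tracking(
    path: str | Path, dialect: TrackingDialect | None = None
) -> list[VelocityTrack]:
    """Read a long-format tracking export into one :class:`VelocityTrack` per subject.

    Gaps in each subject's time grid are filled with missing samples so every
    series is uniformly spaced. Subjects appear in file order.
    """
    dialect = dialect or TrackingDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            na_values=list(dialect.na_values),
            keep_default_na=True,
            dtype={"subject_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty tracking file") from None
    missing_cols = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    if df.empty:
        raise ValueError(f"{path}: tracking file has a header but no rows")
    tracks: list[VelocityTrack] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        times = grp["time_s"].to_numpy(dtype=float)
        vel = grp["velocity_mm_s"].to_numpy(dtype=float)
        if np.isnan(times).any():
            raise ValueError(f"subject {sid!r}: missing time_s values")
        tracks.append(_reconstruct_grid(str(sid), times, vel, dialect))
    logger.info("read %d tracks from %s", len(tracks), path)
    return tracks


def read_metadata(path: str | Path, delimiter: str = ",") -> list[SubjectMeta]:
    """Read the subject metadata table.

    Treatment labels are read as categorical strings even when they look
    numeric (an acclimation temperature of "17" is a group label, not a
    covariate value). ``intro_offset_s``, ``block`` and ``run`` are optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype={"subject_id": str, "treatment": str, "block": str, "run": str},
        float_precision="round_trip",
    )
    for col in ("subject_id", "treatment"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated subject_id {dup.iloc[0]!r}")
    records: list[SubjectMeta] = []
    for i, row in enumerate(df.itertuples(index=False)):
        size = getattr(row, "body_size_mm", float("nan"))
        size = float(size) if size is not None and not pd.isna(size) else float("nan")
        if not np.isnan(size) and size <= 0:
            raise ValueError(f"{path}: row {i + 2}: non-positive body_size_mm {size}")
        offset = getattr(row, "intro_offset_s", 0.0)
        offset = float(offset) if not pd.isna(offset) else 0.0
        records.append(
            SubjectMeta(
                subject_id=str(row.subject_id),
                treatment=str(row.treatment),
                body_size_mm=size,
                intro_offset_s=offset,
                block=str(getattr(row, "block", "") or ""),
                run=str(getattr(row, "run", "") or ""),
            )
        )
    return records


def join_dataset(
    tracks: Iterable[VelocityTrack], meta: Iterable[SubjectMeta]
) -> Dataset:
    """Inner-join tracks and metadata on subject_id.

    Subjects present in only one source are reported (count and ids at WARNING
    level) and excluded — mirroring how an animal lost during handling drops
    out of the analysed set. Each track inherits its metadata row's
    introduction offset.
    """
    tracks = list(tracks)
    meta = list(meta)
    if not tracks or not meta:
        raise ValueError("join_dataset requires non-empty tracks and metadata")
    meta_by_id = {m.subject_id: m for m in meta}
    track_by_id = {t.subject_id: t for t in tracks}
    orphan_tracks = tuple(sid for sid in track_by_id if sid not in meta_by_id)
    orphan_meta = tuple(sid for sid in meta_by_id if sid not in track_by_id)
    shared = [t.subject_id for t in tracks if t.subject_id in meta_by_id]
    if not shared:
        raise ValueError("no subject_id shared between tracks and metadata")
    if orphan_tracks:
        logger.warning(
            "%d track(s) without metadata excluded: %s", len(orphan_tracks), list(orphan_tracks)
        )
    if orphan_meta:
        logger.warning(
            "%d metadata row(s) without a track excluded: %s", len(orphan_meta), list(orphan_meta)
        )
    joined_tracks = [
        dataclasses.replace(track_by_id[sid], intro_offset_s=meta_by_id[sid].intro_offset_s)
        for sid in shared
    ]
    joined_meta = [meta_by_id[sid] for sid in shared]
    return Dataset(
        tracks=joined_tracks,
        meta=joined_meta,
        orphan_track_ids=orphan_tracks,
        orphan_meta_ids=orphan_meta,
    )


def write_tracking(tracks: Sequence[VelocityTrack], path: str | Path) -> None:
    """Write tracks in the canonical long format (missing velocity = empty field)."""
    frames = []
    for t in tracks:
        # shortest round-trip float repr so re-reading reproduces values
        # bit-for-bit; missing velocity is an empty field
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": t.subject_id,
                    "time_s": [repr(float(x)) for x in t.times_s],
                    "velocity_mm_s": [
                        "" if np.isnan(x) else repr(float(x)) for x in t.velocities
                    ],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_metadata(meta: Sequence[SubjectMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in meta],
            "treatment": [m.treatment for m in meta],
            "body_size_mm": [m.body_size_mm for m in meta],
            "intro_offset_s": [m.intro_offset_s for m in meta],
            "block": [m.block for m in meta],
            "run": [m.run for m in meta],
        }
    ).to_csv(path, index=False)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write the per-subject T_imm results table (canonical column order)."""
    cols = [c for c in RESULTS_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results.loc[:, cols].to_csv(path, index=False)
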