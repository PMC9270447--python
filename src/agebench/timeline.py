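"""Timestamped regression datasets on a day-offset axis.

Everything downstream works on :class:`TimestampedDataset`: records ordered by
time, with timestamps expressed as real-valued days since the first record
(day 0 = earliest).  Sub-day resolution is kept as fractional days.  All
windows are half-open ``[start, end)`` so adjacent windows partition records
without double-counting.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimestampedDataset",
    "TimeWindow",
    "ValidationReport",
    "TimelineSummary",
    "TimelineError",
    "TimestampFormatError",
    "FeatureTypeError",
    "MissingDataError",
    "SchemaError",
    "EmptyWindowError",
    "load_timestamped_table",
    "validate_dataset",
    "slice_window",
    "summarize_timeline",
]


class TimelineError(ValueError):
    """Base class for dataset loading/validation problems."""


class TimestampFormatError(TimelineError):
    """A timestamp cell failed to parse as ISO-8601."""


class FeatureTypeError(TimelineError):
    """A feature or target cell is non-numeric."""


class MissingDataError(TimelineError):
    """A feature or target cell is empty/missing."""


class SchemaError(TimelineError):
    """Column naming problem (duplicates, unknown columns)."""


class EmptyWindowError(TimelineError):
    """A slice produced no records."""


@dataclasses.dataclass(frozen=True)
class TimeWindow:
    """Half-open interval ``[start, end)`` in day offsets."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"TimeWindow requires start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        t = np.asarray(t)
        out = (t >= self.start) & (t < self.end)
        return out if out.ndim else bool(out)


@dataclasses.dataclass
class TimestampedDataset:
    """Ordered (timestamp, features, target) records.

    Parameters
    ----------
    name
        Free-text label carried through results.
    timestamps
        Real-valued day offsets, non-decreasing, day 0 = earliest record.
    features
        ``(n_records, n_features)`` numeric matrix, all finite.
    feature_names
        Unique column labels, one per feature.
    target
        Length ``n_records`` numeric vector, all finite.
    """

    name: str
    timestamps: np.ndarray
    features: np.ndarray
    feature_names: list[str]
    target: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.target = np.asarray(self.target, dtype=float)
        self.feature_names = list(self.feature_names)
        n = self.timestamps.shape[0]
        if self.features.shape[0] != n or self.target.shape[0] != n:
            raise TimelineError(
                f"record count mismatch: {n} timestamps, {self.features.shape[0]} feature rows, "
                f"{self.target.shape[0]} targets"
            )
        if self.features.shape[1] != len(self.feature_names):
            raise TimelineError("feature_names length does not match feature matrix width")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("feature_names must be unique")
        if n == 0:
            raise TimelineError("dataset has no records")
        if np.any(np.diff(self.timestamps) < 0):
            raise TimelineError("timestamps must be non-decreasing")
        if not np.all(np.isfinite(self.features)):
            raise MissingDataError("features contain missing/non-finite values")
        if not np.all(np.isfinite(self.target)):
            raise MissingDataError("target contains missing/non-finite values")

    # -- convenience ----------------------------------------------------
    @property
    def n_records(self) -> int:
        return self.timestamps.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def span(self) -> float:
        """Last minus first timestamp, in days."""
        return float(self.timestamps[-1] - self.timestamps[0])

    def window_record_count(self, w: TimeWindow) -> int:
        lo = np.searchsorted(self.timestamps, w.start, side="left")
        hi = np.searchsorted(self.timestamps, w.end, side="left")
        return int(hi - lo)


@dataclasses.dataclass
class ValidationReport:
    """Screening outcome: hard gates (missing data, span) plus warnings."""

    passed: bool
    span_days: float
    n_records: int
    missing_count: int
    abrupt_change_flag: bool
    abrupt_change_times: list[float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class TimelineSummary:
    """Daily target means with a centered moving average (shrinks at edges)."""

    day_grid: np.ndarray
    daily_mean: np.ndarray
    daily_count: np.ndarray
    moving_average: np.ndarray
    ma_window_days: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day_grid,
                "daily_mean": self.daily_mean,
                "daily_count": self.daily_count,
                "moving_average": self.moving_average,
            }
        )


def _check_duplicate_header(path: Path) -> None:
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise SchemaError(f"duplicate column names in {path.name}: {sorted(dupes)}")


def _numeric_column(df: pd.DataFrame, col: str, role: str) -> np.ndarray:
    raw = df[col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header line plus 1-based counting, i.e. the physical file row
        if raw.isna().iloc[row] or (isinstance(raw.iloc[row], str) and raw.iloc[row].strip() == ""):
            raise MissingDataError(f"missing {role} value at file row {row + 2}, column '{col}'")
        raise FeatureTypeError(
            f"non-numeric {role} value {raw.iloc[row]!r} at file row {row + 2}, column '{col}'"
        )
    return values.to_numpy(dtype=float)


def load_timestamped_table(
    path: str | Path,
    timestamp_column: str,
    target_column: str,
    feature_columns: Sequence[str] | str = "auto",
    name: str | None = None,
) -> TimestampedDataset:
    """Load a CSV with an ISO-8601 timestamp column into a :class:`TimestampedDataset`.

    Records are sorted ascending by timestamp and timestamps converted to day
    offsets from the earliest record.  ``feature_columns="auto"`` selects every
    numeric column except the timestamp and target.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_duplicate_header(path)
    df = pd.read_csv(path)
    for col in (timestamp_column, target_column):
        if col not in df.columns:
            raise SchemaError(f"column '{col}' not found in {path.name}")

    ts = pd.to_datetime(df[timestamp_column], format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise TimestampFormatError(
            f"unparseable timestamp {df[timestamp_column].iloc[row]!r} at file row {row + 2}"
        )

    if feature_columns == "auto":
        candidates = [c for c in df.columns if c not in (timestamp_column, target_column)]
        feature_columns = [
            c for c in candidates if pd.to_numeric(df[c], errors="coerce").notna().all()
        ]
    else:
        feature_columns = list(feature_columns)
        for col in feature_columns:
            if col not in df.columns:
                raise SchemaError(f"feature column '{col}' not found in {path.name}")

    target = _numeric_column(df, target_column, "target")
    features = np.column_stack(
        [_numeric_column(df, c, "feature") for c in feature_columns]
    ) if feature_columns else np.empty((len(df), 0))

    order = np.argsort(ts.to_numpy(), kind="stable")
    ts_sorted = ts.to_numpy()[order]
    offsets = (ts_sorted - ts_sorted[0]) / np.timedelta64(1, "s") / 86400.0
    return TimestampedDataset(
        name=name or path.stem,
        timestamps=offsets,
        features=features[order],
        feature_names=list(feature_columns),
        target=target[order],
    )


def _daily_aggregate(ds: TimestampedDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    days = np.floor(ds.timestamps).astype(int)
    grid, inverse, counts = np.unique(days, return_inverse=True, return_counts=True)
    sums = np.bincount(inverse, weights=ds.target)
    return grid, sums / counts, counts


def validate_dataset(
    ds: TimestampedDataset,
    min_span_days: float = 730.0,
    k_sd: float = 6.0,
    rolling_days: int = 7,
) -> ValidationReport:
    """Screen a dataset: span gate, missing data, and an abrupt-change warning.

    The abrupt-change heuristic compares, for each day ``d``, the
    ``rolling_days``-day average of daily target means starting at ``d`` with
    the same-length average ending at ``d - 1``.  A jump exceeding ``k_sd``
    robust standard deviations of the daily means (scale estimated from median
    absolute day-to-day differences, immune to the jump itself) raises the
    flag.  The flag is a warning only and never affects ``passed``.
    """
    # Constructor already rejects non-finite cells, so missing_count is 0 for
    # any live dataset; reported for interface completeness.
    missing = int(np.count_nonzero(~np.isfinite(ds.features)) + np.count_nonzero(~np.isfinite(ds.target)))
    grid, daily_mean, _ = _daily_aggregate(ds)

    flagged: list[float] = []
    if len(daily_mean) >= 2 * rolling_days + 1:
        diffs = np.abs(np.diff(daily_mean))
        # robust sigma of daily means: diff of two iid N(0, s^2) has MAD
        # 0.6745*s*sqrt(2) => s = 1.4826*median|diff|/sqrt(2)
        sigma = 1.4826 * float(np.median(diffs)) / np.sqrt(2.0)
        cum = np.concatenate([[0.0], np.cumsum(daily_mean)])
        w = rolling_days
        # forward mean over [i, i+w), backward mean over [i-w, i)
        for i in range(w, len(daily_mean) - w + 1):
            fwd = (cum[i + w] - cum[i]) / w
            back = (cum[i] - cum[i - w]) / w
            if abs(fwd - back) > k_sd * sigma and sigma > 0:
                flagged.append(float(grid[i]))

    return ValidationReport(
        passed=(missing == 0 and ds.span >= min_span_days),
        span_days=ds.span,
        n_records=ds.n_records,
        missing_count=missing,
        abrupt_change_flag=bool(flagged),
        abrupt_change_times=flagged,
    )


def slice_window(ds: TimestampedDataset, w: TimeWindow) -> TimestampedDataset:
    """Records with ``start <= timestamp < end``; ordering and columns preserved."""
    lo = np.searchsorted(ds.timestamps, w.start, side="left")
    hi = np.searchsorted(ds.timestamps, w.end, side="left")
    if hi <= lo:
        raise EmptyWindowError(f"window [{w.start}, {w.end}) contains no records of '{ds.name}'")
    return TimestampedDataset(
        name=ds.name,
        timestamps=ds.timestamps[lo:hi].copy(),
        features=ds.features[lo:hi].copy(),
        feature_names=list(ds.feature_names),
        target=ds.target[lo:hi].copy(),
    )


def summarize_timeline(ds: TimestampedDataset, ma_window_days: int = 7) -> TimelineSummary:
    """Daily means of the target plus a centered moving average.

    The moving average is taken over the listed (observed) days with a
    centered window of ``ma_window_days`` entries, shrinking at the edges.
    """
    grid, daily_mean, counts = _daily_aggregate(ds)
    ma = (
        pd.Series(daily_mean)
        .rolling(ma_window_days, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return TimelineSummary(
        day_grid=grid,
        daily_mean=daily_mean,
        daily_count=counts,
        moving_average=ma,
        ma_window_days=ma_window_days,
    )
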