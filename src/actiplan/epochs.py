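"""Raw epoch-count processing: non-wear detection, wear-time validation
and intensity summarisation.

The processing chain mirrors a widely used wear-time validation
procedure for waist-worn accelerometers recording vertical-axis counts
in short (here 5-s) epochs:

1. counts are re-integrated to 60-s epochs so that every epoch is a
   counts-per-minute (cpm) value directly comparable to the published
   intensity cut-points;
2. maximal runs of consecutive zero-cpm minutes strictly longer than
   20 min are flagged as non-wear (no spike allowance);
3. a day is *valid* when its wear time strictly exceeds 600 min;
4. wear minutes are classified into sedentary/light/moderate/vigorous
   bands, MVPA being moderate + vigorous, and total counts are the sum
   over the whole day;
5. subjects enter the analysis cohort only with at least 21 valid days.

Day boundaries follow the calendar date of each epoch's start
timestamp; partial first/last days are processed like any other day and
stand or fall by the wear-time rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date as Date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset, DailySummary, summaries_to_frame
from .cutpoints import BANDS, CutPointScheme, FREEDSON_ADULT
from .exceptions import FormatError, InvalidConfigError

NONWEAR_RUN_MIN = 20  # zero runs must be STRICTLY longer than this
VALID_DAY_MIN = 600  # wear must STRICTLY exceed this
MIN_VALID_DAYS = 21  # subject inclusion threshold


@dataclass(frozen=True)
class EpochSeries:
    """A uniformly spaced stream of epoch counts for one subject.

    ``start`` is the timestamp of the first epoch; epoch ``i`` begins at
    ``start + i * epoch_s`` seconds.  Counts are vertical-axis activity
    counts per epoch, non-negative.
    """

    subject_id: str
    start: pd.Timestamp
    epoch_s: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not (1 <= self.epoch_s <= 60 and 60 % self.epoch_s == 0):
            raise InvalidConfigError(
                f"epoch_s must divide 60 and lie in 1..60, got {self.epoch_s}"
            )
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise InvalidConfigError("counts must be one-dimensional")
        if len(counts) and counts.min() < 0:
            raise InvalidConfigError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "start", pd.Timestamp(self.start))

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self.counts)) * self.epoch_s, unit="s"
        )

    @property
    def date(self) -> Date:
        return self.start.date()


def read_epoch_file(path, *, delimiter: str | None = None) -> list[EpochSeries]:
    """Read a plain tabular epoch file into per-(subject, date) series.

    Expected columns: ``subject_id``, ``timestamp`` (ISO-8601),
    ``counts``.  The delimiter is auto-detected among comma and tab
    unless given.  Within each subject-day the timestamps must be
    strictly increasing and uniformly spaced; violations raise
    :class:`FormatError` naming the offending row.
    """
    with open(path) as fh:
        head = fh.readline()
    if not head:
        raise FormatError(f"{path}: empty file")
    if delimiter is None:
        delimiter = "\t" if head.count("\t") >= head.count(",") else ","
    df = pd.read_csv(path, sep=delimiter)
    required = {"subject_id", "timestamp", "counts"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    neg = df.index[df["counts"] < 0]
    if len(neg):
        raise FormatError(f"{path}: negative count at data row {neg[0] + 1}")
    df["subject_id"] = df["subject_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    out: list[EpochSeries] = []
    for (sid, day), grp in df.groupby(
        ["subject_id", df["timestamp"].dt.date], sort=True
    ):
        grp = grp.sort_values("timestamp", kind="stable")
        ts = grp["timestamp"].to_numpy()
        if len(ts) > 1:
            gaps = np.diff(ts).astype("timedelta64[s]").astype(int)
            if np.any(gaps == 0):
                row = grp.index[int(np.argmax(gaps == 0)) + 1] + 1
                raise FormatError(
                    f"{path}: duplicate timestamp for subject {sid} at data row {row}"
                )
            if len(set(gaps)) > 1:
                bad = int(np.argmax(gaps != gaps[0])) + 1
                row = grp.index[bad] + 1
                raise FormatError(
                    f"{path}: non-uniform epoch spacing for subject {sid} "
                    f"at data row {row}"
                )
            epoch_s = int(gaps[0])
        else:
            epoch_s = 5  # single row: spacing unknowable; assume the default
        out.append(
            EpochSeries(
                subject_id=sid,
                start=pd.Timestamp(ts[0]),
                epoch_s=epoch_s,
                counts=grp["counts"].to_numpy(),
            )
        )
    return out


def write_epoch_stream(series: Iterable[EpochSeries], path, *, delimiter=",") -> None:
    """Write epoch series as plain text (subject_id, timestamp, counts)."""
    frames = [
        pd.DataFrame(
            {
                "subject_id": s.subject_id,
                "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                "counts": s.counts,
            }
        )
        for s in series
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["subject_id", "timestamp", "counts"])
    )
    df.to_csv(path, sep=delimiter, index=False)


def reintegrate(series: EpochSeries, target_epoch_s: int = 60) -> EpochSeries:
    """Sum counts over consecutive blocks to a coarser epoch length.

    A trailing block with fewer than ``target_epoch_s / epoch_s`` source
    epochs is dropped.  ``target_epoch_s == epoch_s`` is the identity.
    """
    if target_epoch_s % series.epoch_s != 0:
        raise InvalidConfigError(
            f"target epoch {target_epoch_s}s is not a multiple of {series.epoch_s}s"
        )
    k = target_epoch_s // series.epoch_s
    if k == 1:
        return series
    n_blocks = len(series.counts) // k
    summed = series.counts[: n_blocks * k].reshape(n_blocks, k).sum(axis=1)
    return replace(series, epoch_s=target_epoch_s, counts=summed)


def detect_nonwear(series_60s: EpochSeries) -> np.ndarray:
    """Boolean wear mask for a 60-s epoch series.

    Maximal runs of consecutive zero-count minutes strictly longer than
    20 min are non-wear (``False``); every other epoch — including zero
    runs of exactly 20 min — is wear.
    """
    if series_60s.epoch_s != 60:
        raise InvalidConfigError("non-wear detection operates on 60-s epochs")
    zero = series_60s.counts == 0
    wear = np.ones(len(zero), dtype=bool)
    if not zero.any():
        return wear
    # run-length encode the zero indicator
    change = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(zero)]))
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) > NONWEAR_RUN_MIN:
            wear[s:e] = False
    return wear


def summarize_day(
    series_60s: EpochSeries,
    wear_mask: np.ndarray | None = None,
    cutpoints: CutPointScheme = FREEDSON_ADULT,
) -> DailySummary:
    """Summarise a 60-s subject-day series into a :class:`DailySummary`.

    Wear minutes are classified by cpm band; ``total_counts`` sums over
    the whole day (non-wear epochs are zero by construction of the
    rule).  Validity is wear > 600 min, strictly.
    """
    if series_60s.epoch_s != 60:
        raise InvalidConfigError("daily summaries are computed from 60-s epochs")
    if wear_mask is None:
        wear_mask = detect_nonwear(series_60s)
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if wear_mask.shape != series_60s.counts.shape:
        raise InvalidConfigError("wear mask is not aligned to the series")
    cpm = series_60s.counts[wear_mask]
    minutes = np.bincount(cutpoints.classify(cpm), minlength=len(BANDS)) if len(
        cpm
    ) else np.zeros(len(BANDS), dtype=int)
    return DailySummary(
        subject_id=series_60s.subject_id,
        date=series_60s.date,
        wear_min=float(wear_mask.sum()),
        sedentary_min=float(minutes[0]),
        light_min=float(minutes[1]),
        moderate_min=float(minutes[2]),
        vigorous_min=float(minutes[3]),
        total_counts=float(series_60s.counts.sum()),
    )


def process_stream(
    series: Sequence[EpochSeries], cutpoints: CutPointScheme = FREEDSON_ADULT
) -> pd.DataFrame:
    """Run the full chain (reintegrate → non-wear → summarise) per day."""
    summaries = []
    for s in series:
        s60 = reintegrate(s, 60)
        summaries.append(summarize_day(s60, detect_nonwear(s60), cutpoints))
    return summaries_to_frame(summaries)


def include_subjects(
    summaries: pd.DataFrame | Iterable[DailySummary],
    min_valid_days: int = MIN_VALID_DAYS,
) -> CohortDataset:
    """Apply the cohort inclusion rule.

    Keeps only valid days, then only subjects with at least
    ``min_valid_days`` of them.  Excluded subjects are reported on the
    returned cohort's ``exclusions`` table with their valid-day count.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = summaries_to_frame(summaries)
    if summaries.empty:
        import warnings

        warnings.warn("include_subjects received an empty summary table")
        empty = summaries.iloc[0:0]
        return CohortDataset(
            empty.drop(columns=["valid"], errors="ignore"),
            label="all_days",
            exclusions=pd.DataFrame(columns=["subject_id", "n_valid_days", "reason"]),
        )
    valid = summaries[summaries["valid"].astype(bool)]
    counts = valid.groupby("subject_id").size()
    all_subjects = summaries["subject_id"].unique()
    kept = set(counts[counts >= min_valid_days].index)
    excl_rows = [
        {
            "subject_id": sid,
            "n_valid_days": int(counts.get(sid, 0)),
            "reason": f"fewer than {min_valid_days} valid days",
        }
        for sid in all_subjects
        if sid not in kept
    ]
    data = (
        valid[valid["subject_id"].isin(kept)]
        .drop(columns=["valid"])
        .sort_values(["subject_id", "date"], kind="stable")
        .reset_index(drop=True)
    )
    return CohortDataset(
        data,
        label="all_days",
        exclusions=pd.DataFrame(
            excl_rows, columns=["subject_id", "n_valid_days", "reason"]
        ),
    )
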