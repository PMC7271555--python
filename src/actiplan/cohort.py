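"""Daily-summary and cohort containers plus their plain-text I/O.

A *daily summary* is one subject-day after wear-time processing: wear
minutes, minutes per intensity band, total counts and the validity flag
(wear > 600 min).  A :class:`CohortDataset` is a table of such rows (or,
for simulated day-level cohorts, of plain outcome values) keyed by
subject and date, together with provenance: which protocol scheme
produced it and under which seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from datetime import date as Date
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import FormatError

SUMMARY_COLUMNS = [
    "subject_id",
    "date",
    "wear_min",
    "sedentary_min",
    "light_min",
    "moderate_min",
    "vigorous_min",
    "mvpa_min",
    "total_counts",
    "valid",
]

#: Outcome columns a variance decomposition may be asked for.
OUTCOME_COLUMNS = [
    "sedentary_min",
    "light_min",
    "moderate_min",
    "vigorous_min",
    "mvpa_min",
    "total_counts",
]


@dataclass(frozen=True)
class DailySummary:
    """Wear-time and intensity summary of one subject-day."""

    subject_id: str
    date: Date
    wear_min: float
    sedentary_min: float
    light_min: float
    moderate_min: float
    vigorous_min: float
    total_counts: float

    @property
    def mvpa_min(self) -> float:
        return self.moderate_min + self.vigorous_min

    @property
    def valid(self) -> bool:
        """A valid monitoring day has strictly more than 600 wear minutes."""
        return self.wear_min > 600.0

    def as_row(self) -> dict:
        d = asdict(self)
        d["mvpa_min"] = self.mvpa_min
        d["valid"] = self.valid
        return d


def summaries_to_frame(summaries: Iterable[DailySummary]) -> pd.DataFrame:
    rows = [s.as_row() for s in summaries]
    if not rows:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.DataFrame(rows)[SUMMARY_COLUMNS]


@dataclass
class CohortDataset:
    """A cohort table with provenance.

    ``data`` always carries ``subject_id`` and ``date`` columns; the
    remaining columns are outcomes (the daily-summary columns, or a
    single ``value`` column for simulated day-level cohorts).
    """

    data: pd.DataFrame
    label: str = "all_days"
    seed: int | None = None
    source: str = ""
    exclusions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = {"subject_id", "date"} - set(self.data.columns)
        if missing:
            raise FormatError(f"cohort table lacks required columns: {sorted(missing)}")

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_days(self) -> int:
        return len(self.data)

    def days_per_subject(self) -> pd.Series:
        return self.data.groupby("subject_id", sort=True).size()

    def grouped(self, column: str) -> dict[str, np.ndarray]:
        """Outcome values grouped by subject, for variance decomposition."""
        if column not in self.data.columns:
            raise KeyError(f"no outcome column {column!r} in cohort")
        return {
            str(sid): grp[column].to_numpy(dtype=float)
            for sid, grp in self.data.groupby("subject_id", sort=True)
        }

    def sorted_copy(self) -> "CohortDataset":
        df = self.data.sort_values(["subject_id", "date"], kind="stable").reset_index(
            drop=True
        )
        return CohortDataset(df, self.label, self.seed, self.source, self.exclusions)


def write_cohort_tsv(cohort: CohortDataset, path) -> None:
    """Write a cohort as TSV with ``#``-prefixed provenance header lines."""
    with open(path, "w") as fh:
        fh.write(f"# actiplan cohort\n# label: {cohort.label}\n")
        if cohort.seed is not None:
            fh.write(f"# seed: {cohort.seed}\n")
        if cohort.source:
            fh.write(f"# source: {cohort.source}\n")
        cohort.data.to_csv(fh, sep="\t", index=False)


def read_cohort_tsv(path) -> CohortDataset:
    """Read a cohort TSV written by :func:`write_cohort_tsv`.

    Plain headerless-provenance TSV files (just the column header row)
    are accepted too, with default provenance.
    """
    label, seed, source = "all_days", None, ""
    lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("label:"):
                    label = body.split(":", 1)[1].strip()
                elif body.startswith("seed:"):
                    seed = int(body.split(":", 1)[1])
                elif body.startswith("source:"):
                    source = body.split(":", 1)[1].strip()
            else:
                lines.append(line)
    if not lines:
        raise FormatError(f"{path}: no tabular content")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t")
    df["subject_id"] = df["subject_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return CohortDataset(df, label=label, seed=seed, source=str(path))
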