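"""Measurement-protocol subsets of a valid-day cohort.

Four protocol schemes are supported, mimicking common accelerometer
study designs applied to a cohort where every subject has 21-28 valid
monitoring days:

- ``all_days``     — every valid day (identity);
- ``first7``       — each subject's 7 chronologically earliest valid days;
- ``random7``      — 7 valid days sampled uniformly without replacement
                     per subject;
- ``random3of7``   — 3 days sampled from the first-7 subset.

"First" days are the first *valid* days, not calendar days: analysis
cohorts contain only valid days, and the 3-of-7 scheme needs 7 usable
days to draw from.  Random sampling uses an independent substream per
subject (derived from the seed and a stable hash of the subject id), so
changing cohort composition never reshuffles other subjects, and the
chronological order of selected days is restored after sampling.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .exceptions import InvalidConfigError

SCHEMES = ("all_days", "first7", "random7", "random3of7")


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(str(subject_id).encode())])


def _check_min_days(cohort: CohortDataset, k: int, what: str) -> None:
    counts = cohort.days_per_subject()
    short = counts[counts < k]
    if len(short):
        raise InvalidConfigError(
            f"{what} needs at least {k} valid days per subject; too few for "
            f"subjects: {', '.join(map(str, short.index.tolist()))}"
        )


def subset_all(cohort: CohortDataset) -> CohortDataset:
    """The full valid-day dataset, relabelled ``all_days``."""
    out = cohort.sorted_copy()
    out.label = "all_days"
    out.source = cohort.source
    return out


def subset_first_k(cohort: CohortDataset, k: int = 7, *, label=None) -> CohortDataset:
    """Each subject's ``k`` chronologically earliest valid days."""
    _check_min_days(cohort, k, f"first-{k} subset")
    df = cohort.data.sort_values(["subject_id", "date"], kind="stable")
    out = df.groupby("subject_id", sort=True).head(k).reset_index(drop=True)
    return CohortDataset(
        out, label=label or f"first{k}", seed=cohort.seed, source=cohort.source
    )


def subset_random_k(
    cohort: CohortDataset, k: int = 7, seed: int = 0, *, label=None
) -> CohortDataset:
    """``k`` valid days per subject, uniform without replacement."""
    _check_min_days(cohort, k, f"random-{k} subset")
    parts = []
    for sid, grp in cohort.data.sort_values(
        ["subject_id", "date"], kind="stable"
    ).groupby("subject_id", sort=True):
        rng = _subject_rng(seed, sid)
        idx = np.sort(rng.choice(len(grp), size=k, replace=False))
        parts.append(grp.iloc[idx])
    out = pd.concat(parts, ignore_index=True)
    return CohortDataset(
        out, label=label or f"random{k}", seed=seed, source=cohort.source
    )


def subset_random_from_first(
    cohort: CohortDataset, k: int = 3, first: int = 7, seed: int = 0
) -> CohortDataset:
    """``k`` random days from each subject's first ``first`` valid days."""
    if k > first:
        raise InvalidConfigError(f"cannot draw {k} days from the first {first}")
    week = subset_first_k(cohort, first)
    out = subset_random_k(week, k, seed, label=f"random{k}of{first}")
    return out


def make_subset(cohort: CohortDataset, scheme: str, seed: int = 0) -> CohortDataset:
    """Dispatch on a scheme label (see :data:`SCHEMES`)."""
    if scheme in ("all", "all_days"):
        return subset_all(cohort)
    if scheme == "first7":
        return subset_first_k(cohort, 7)
    if scheme == "random7":
        return subset_random_k(cohort, 7, seed)
    if scheme == "random3of7":
        return subset_random_from_first(cohort, 3, 7, seed)
    raise InvalidConfigError(f"unknown protocol scheme {scheme!r}; choose from {SCHEMES}")
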