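"""Variance-component decomposition via unbalanced one-way random-effects ANOVA.

The model is ``y_ij = mu + b_i + e_ij`` with subject effects
``b_i ~ (0, sigma_b2)`` and day-to-day noise ``e_ij ~ (0, sigma_w2)``,
subject being the only random factor.  For ``a`` subjects with group
sizes ``m_i`` (total ``N``) the ANOVA (method-of-moments) estimator is

    MS_between = sum_i m_i (ybar_i - ybar)^2 / (a - 1)
    MS_within  = sum_ij (y_ij - ybar_i)^2 / (N - a)
    k0         = (N - sum_i m_i^2 / N) / (a - 1)
    sigma_w2   = MS_within
    sigma_b2   = max(0, (MS_between - MS_within) / k0)

with the intraclass correlation ICC = sigma_b2 / (sigma_b2 + sigma_w2).
``k0`` is the effective group size; for balanced data it equals the
common ``m`` and the estimator reduces to the textbook balanced one-way
ANOVA.  A negative raw between-subject variance is truncated to zero
and flagged, the standard behaviour of this estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .exceptions import DomainError, EstimationError


@dataclass(frozen=True)
class VarianceComponents:
    """Point estimates from a one-way random-effects decomposition."""

    sigma_b2: float  # between-subject variance
    sigma_w2: float  # within-subject (day-to-day) variance
    icc: float
    ms_between: float
    ms_within: float
    k0: float  # effective group size
    n_subjects: int
    n_obs: int
    grand_mean: float
    truncated: bool = False  # raw between-variance was negative, clamped to 0

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "VarianceComponents":
        with open(path) as fh:
            return cls(**json.load(fh))


def icc_from_components(sigma_b2: float, sigma_w2: float) -> float:
    """ICC = sigma_b2 / (sigma_b2 + sigma_w2).

    The ICC is the share of total variance attributable to stable
    between-subject differences; e.g. (100, 25) and (10, 2.5) both give
    0.8 although the absolute day-to-day fluctuation differs tenfold.
    """
    if sigma_b2 < 0 or sigma_w2 < 0:
        raise DomainError("variance components must be non-negative")
    total = sigma_b2 + sigma_w2
    if total == 0:
        raise DomainError("ICC is undefined when both components are zero")
    return sigma_b2 / total


def _groups_from(data, column: str | None, group_col: str) -> list[np.ndarray]:
    if isinstance(data, CohortDataset):
        if column is None:
            raise EstimationError("an outcome column name is required for a cohort")
        return list(data.grouped(column).values())
    if isinstance(data, pd.DataFrame):
        if column is None:
            raise EstimationError("an outcome column name is required for a DataFrame")
        return [
            grp[column].to_numpy(dtype=float)
            for _, grp in data.groupby(group_col, sort=True)
        ]
    if isinstance(data, Mapping):
        return [np.asarray(v, dtype=float) for v in data.values()]
    return [np.asarray(g, dtype=float) for g in data]


def anova_decompose(
    data,
    column: str | None = None,
    *,
    group_col: str = "subject_id",
    mean_of: str = "observations",
) -> VarianceComponents:
    """Decompose grouped daily values into variance components.

    Parameters
    ----------
    data
        A :class:`~actiplan.cohort.CohortDataset` or DataFrame (with
        ``column`` naming the outcome), a mapping of subject to value
        array, or a plain sequence of per-subject arrays.
    mean_of
        ``"observations"`` (default): grand mean over all days, so
        subjects with more days weigh more; ``"subjects"``: unweighted
        mean of subject means.

    Raises
    ------
    EstimationError
        Fewer than two subjects, or no subject with two observations.
    """
    groups = [g for g in _groups_from(data, column, group_col) if len(g) > 0]
    a = len(groups)
    if a < 2:
        raise EstimationError(f"need at least 2 subjects, got {a}")
    sizes = np.array([len(g) for g in groups], dtype=float)
    N = int(sizes.sum())
    if N <= a:
        raise EstimationError(
            "no within-subject replication: every subject has a single day"
        )
    means = np.array([g.mean() for g in groups])
    y_all = np.concatenate(groups)
    grand = float(y_all.mean())

    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    k0 = (N - float(np.sum(sizes**2)) / N) / (a - 1)

    raw_b = (ms_between - ms_within) / k0
    truncated = raw_b < 0
    sigma_b2 = max(0.0, raw_b)
    sigma_w2 = ms_within
    icc = 0.0 if sigma_b2 + sigma_w2 == 0 else sigma_b2 / (sigma_b2 + sigma_w2)

    if mean_of == "subjects":
        grand = float(means.mean())
    elif mean_of != "observations":
        raise EstimationError(f"mean_of must be 'observations' or 'subjects', got {mean_of!r}")

    return VarianceComponents(
        sigma_b2=float(sigma_b2),
        sigma_w2=float(sigma_w2),
        icc=float(icc),
        ms_between=float(ms_between),
        ms_within=float(ms_within),
        k0=float(k0),
        n_subjects=a,
        n_obs=N,
        grand_mean=grand,
        truncated=bool(truncated),
    )


def within_cv(components: VarianceComponents) -> float:
    """Within-subject coefficient of variation: sqrt(sigma_w2) / mean.

    How much one individual's days fluctuate relative to their level;
    the quantity entering the habitual-days planner.
    """
    if components.grand_mean <= 0:
        raise DomainError("within-subject CV is undefined for non-positive mean")
    return float(np.sqrt(components.sigma_w2) / components.grand_mean)
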