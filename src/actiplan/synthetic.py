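"""Synthetic cohorts with known variance structure.

Two generators live here.

:func:`generate_daily_cohort` emulates a free-living monitoring study at
the day level: each subject has a latent habitual activity level drawn
around the population mean with between-subject variance ``sigma_b2``,
and each monitored day scatters around that level with within-subject
variance ``sigma_w2``.  Day values may be normal or — for right-skewed
outcomes such as vigorous activity — lognormal with the log-scale
parameters solved so the *observed-scale* mean and variance components
match the configured targets exactly.

:func:`generate_epoch_day` builds a raw epoch-count day from an explicit
bout plan (non-wear, sedentary, light, moderate, vigorous bouts of known
duration) together with its ground-truth daily summary, so the full
wear-time processing chain can be verified to reproduce planned truth
exactly.

Randomness is reproducible: each subject gets an independent RNG
substream derived from the master seed, so enlarging a cohort never
perturbs existing subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset, DailySummary
from .cutpoints import BANDS, CutPointScheme, FREEDSON_ADULT
from .epochs import NONWEAR_RUN_MIN, EpochSeries
from .exceptions import InvalidConfigError, InvalidPlanError

#: First monitoring date of simulated cohorts (a Monday; arbitrary anchor).
BASE_DATE = Date(2020, 1, 6)

BOUT_KINDS = ("nonwear",) + BANDS


@dataclass(frozen=True)
class GroundTruth:
    """Simulation truth stored alongside a generated cohort."""

    mu: float
    sigma_b2: float
    sigma_w2: float
    subject_means: pd.Series  # latent per-subject habitual levels


@dataclass(frozen=True)
class DailyCohortConfig:
    """Configuration of a day-level cohort simulation.

    Parameters
    ----------
    mu
        Grand mean of the daily outcome (outcome units, e.g. min/day).
    sigma_b2, sigma_w2
        Between- and within-subject variances on the observed scale
        (outcome units squared).
    n_subjects, days_per_subject
        Cohort dimensions; ``days_per_subject`` may be a single integer
        or one integer per subject.
    missing_rate
        Probability in ``[0, 1)`` that any given day is dropped
        completely at random.
    family
        ``"normal"`` or ``"lognormal"`` day-value distribution.
    truncate_at_zero
        Clip negative normal-family day values at 0 (off by default;
        negative values exercise estimator robustness).
    """

    mu: float
    sigma_b2: float
    sigma_w2: float
    n_subjects: int
    days_per_subject: int | Sequence[int] = 28
    missing_rate: float = 0.0
    family: str = "normal"
    truncate_at_zero: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigError(f"n_subjects must be positive, got {self.n_subjects}")
        if self.sigma_b2 < 0 or self.sigma_w2 < 0:
            raise InvalidConfigError("variance components must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if self.family not in ("normal", "lognormal"):
            raise InvalidConfigError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and self.mu <= 0:
            raise InvalidConfigError("lognormal family requires mu > 0")
        for m in self.days_list():
            if m < 1:
                raise InvalidConfigError("days_per_subject entries must be positive")

    def days_list(self) -> list[int]:
        if isinstance(self.days_per_subject, (int, np.integer)):
            return [int(self.days_per_subject)] * self.n_subjects
        days = [int(d) for d in self.days_per_subject]
        if len(days) != self.n_subjects:
            raise InvalidConfigError(
                f"days_per_subject has {len(days)} entries for {self.n_subjects} subjects"
            )
        return days


def _lognormal_params(mu: float, sigma_b2: float, sigma_w2: float):
    """Solve log-scale parameters so observed-scale moments match.

    With subject effects ``a_i ~ N(alpha, tau_b2)`` and day noise
    ``e_ij ~ N(0, tau_w2)``, ``y = exp(a_i + e_ij)`` has mean
    ``exp(alpha + (tau_b2 + tau_w2)/2)``, between-subject variance
    ``mu^2 (e^{tau_b2} - 1)`` and mean within-subject variance
    ``mu^2 (e^{tau_w2} - 1) e^{tau_b2}``; inverting gives closed forms.
    """
    tau_b2 = np.log1p(sigma_b2 / mu**2)
    tau_w2 = np.log1p(sigma_w2 / (mu**2 + sigma_b2))
    alpha = np.log(mu) - (tau_b2 + tau_w2) / 2
    return alpha, tau_b2, tau_w2


def generate_daily_cohort(config: DailyCohortConfig) -> CohortDataset:
    """Simulate a day-level cohort; ground truth rides on ``.truth``.

    Returns a :class:`CohortDataset` whose table has columns
    ``subject_id``, ``date`` and ``value``, restricted to retained
    (non-missing) days.  The returned object carries a
    :class:`GroundTruth` attribute with the latent subject means.
    """
    days = config.days_list()
    width = len(str(config.n_subjects))
    frames = []
    subject_means = {}
    if config.family == "lognormal":
        alpha, tau_b2, tau_w2 = _lognormal_params(
            config.mu, config.sigma_b2, config.sigma_w2
        )
    for i, m in enumerate(days):
        rng = np.random.default_rng([config.seed, i])
        sid = f"S{i + 1:0{width}d}"
        if config.family == "normal":
            b = config.mu + np.sqrt(config.sigma_b2) * rng.standard_normal()
            y = b + np.sqrt(config.sigma_w2) * rng.standard_normal(m)
            if config.truncate_at_zero:
                y = np.clip(y, 0.0, None)
            latent = b
        else:
            a = alpha + np.sqrt(tau_b2) * rng.standard_normal()
            y = np.exp(a + np.sqrt(tau_w2) * rng.standard_normal(m))
            latent = np.exp(a + tau_w2 / 2)  # conditional day-level mean
        keep = (
            rng.random(m) >= config.missing_rate
            if config.missing_rate > 0
            else np.ones(m, dtype=bool)
        )
        dates = [BASE_DATE + timedelta(days=j) for j in range(m)]
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "date": [d for d, k in zip(dates, keep) if k],
                    "value": y[keep],
                }
            )
        )
        subject_means[sid] = float(latent)
    data = pd.concat(frames, ignore_index=True)
    cohort = CohortDataset(
        data, label="simulated", seed=config.seed, source="generate_daily_cohort"
    )
    cohort.truth = GroundTruth(
        mu=config.mu,
        sigma_b2=config.sigma_b2,
        sigma_w2=config.sigma_w2,
        subject_means=pd.Series(subject_means, name="subject_mean"),
    )
    return cohort


# ---------------------------------------------------------------------------
# Epoch-level day plans


@dataclass(frozen=True)
class EpochDayPlan:
    """A planned subject-day of wear/non-wear and intensity bouts.

    ``bouts`` is an ordered list of ``(duration_min, kind)`` pairs with
    ``kind`` one of ``nonwear, sedentary, light, moderate, vigorous``;
    durations are whole minutes summing to at most 1440.  Non-wear bouts
    emit all-zero epochs; each wear minute receives a cpm value sampled
    strictly inside its band's cut-point interval (or supplied by
    ``count_sampler``, a mapping/callable from kind to cpm).
    """

    subject_id: str
    date: Date
    bouts: tuple
    epoch_s: int = 5
    count_sampler: Mapping[str, float] | Callable[[str, np.random.Generator], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bouts", tuple((int(d), str(k)) for d, k in self.bouts))
        if not (1 <= self.epoch_s <= 60 and 60 % self.epoch_s == 0):
            raise InvalidPlanError(f"epoch_s must divide 60, got {self.epoch_s}")
        total = 0
        for dur, kind in self.bouts:
            if kind not in BOUT_KINDS:
                raise InvalidPlanError(f"unknown bout kind {kind!r}")
            if dur < 1:
                raise InvalidPlanError("bout durations must be positive whole minutes")
            total += dur
        if total > 1440:
            raise InvalidPlanError(f"bouts sum to {total} min > 1440")


def _sample_cpm(
    kind: str,
    plan: EpochDayPlan,
    cutpoints: CutPointScheme,
    rng: np.random.Generator,
) -> int:
    low, high = cutpoints.band_interval(kind)
    if plan.count_sampler is not None:
        sampler = plan.count_sampler
        cpm = sampler(kind, rng) if callable(sampler) else sampler[kind]
        cpm = float(cpm)
        if not (low < cpm < high):
            raise InvalidPlanError(
                f"sampled cpm {cpm} is not strictly inside the {kind} band "
                f"[{low}, {high})"
            )
        return int(round(cpm))
    # default: integer uniform strictly inside the band; the open-ended
    # vigorous band is capped at 3x its lower bound
    hi = int(min(high, 3 * cutpoints.vigorous_min)) - 1
    return int(rng.integers(int(low) + 1, hi + 1))


def _truth_summary(
    plan: EpochDayPlan, minute_cpm: np.ndarray, cutpoints: CutPointScheme
) -> DailySummary:
    """Planned ground truth from minute-level bout arithmetic.

    Works on the minute sequence directly (no epoch mask machinery):
    zero minutes occur exactly in non-wear bouts because wear cpm is
    strictly positive; maximal zero runs longer than 20 min are
    non-wear, shorter ones count as (zero-cpm) sedentary wear.
    """
    wear_cpm = []
    for is_zero, grp in itertools.groupby(minute_cpm, key=lambda c: c == 0):
        run = list(grp)
        if is_zero and len(run) > NONWEAR_RUN_MIN:
            continue
        wear_cpm.extend(run)
    wear_cpm = np.asarray(wear_cpm, dtype=float)
    minutes = (
        np.bincount(cutpoints.classify(wear_cpm), minlength=len(BANDS))
        if len(wear_cpm)
        else np.zeros(len(BANDS), dtype=int)
    )
    return DailySummary(
        subject_id=plan.subject_id,
        date=plan.date,
        wear_min=float(len(wear_cpm)),
        sedentary_min=float(minutes[0]),
        light_min=float(minutes[1]),
        moderate_min=float(minutes[2]),
        vigorous_min=float(minutes[3]),
        total_counts=float(minute_cpm.sum()),
    )


def generate_epoch_day(
    plan: EpochDayPlan, cutpoints: CutPointScheme = FREEDSON_ADULT
) -> tuple[EpochSeries, DailySummary]:
    """Emit the epoch stream of a planned day plus its ground truth.

    The stream starts at midnight of the plan date and covers exactly
    the planned bouts; each wear minute's cpm is split evenly over its
    epochs (remainder counts go to the earliest epochs) so that
    re-integration to 60 s recovers the minute cpm exactly.
    """
    rng = np.random.default_rng(plan.seed)
    minute_cpm_parts = []
    for dur, kind in plan.bouts:
        if kind == "nonwear":
            minute_cpm_parts.append(np.zeros(dur, dtype=np.int64))
        else:
            minute_cpm_parts.append(
                np.array(
                    [_sample_cpm(kind, plan, cutpoints, rng) for _ in range(dur)],
                    dtype=np.int64,
                )
            )
    minute_cpm = (
        np.concatenate(minute_cpm_parts) if minute_cpm_parts else np.zeros(0, np.int64)
    )

    per_min = 60 // plan.epoch_s
    base, rem = np.divmod(minute_cpm, per_min)
    epoch_counts = (
        base[:, None] + (np.arange(per_min)[None, :] < rem[:, None])
    ).reshape(-1)

    series = EpochSeries(
        subject_id=plan.subject_id,
        start=pd.Timestamp(plan.date),
        epoch_s=plan.epoch_s,
        counts=epoch_counts,
    )
    return series, _truth_summary(plan, minute_cpm, cutpoints)


#: Bout-kind sampling weights for random plans: mostly non-wear and
#: sedentary time, a sliver of vigorous — the shape of a free-living day.
_KIND_WEIGHTS = {
    "nonwear": 0.30,
    "sedentary": 0.30,
    "light": 0.20,
    "moderate": 0.12,
    "vigorous": 0.08,
}


def random_epoch_day_plan(
    rng: np.random.Generator,
    subject_id: str = "S1",
    date: Date = BASE_DATE,
    epoch_s: int = 5,
    max_bouts: int = 10,
) -> EpochDayPlan:
    """Draw a random bout plan covering a random fraction of a day.

    Bout kinds, counts and durations vary freely, so resulting days
    range from all-non-wear to fully worn and straddle both the 20-min
    non-wear and the 600-min valid-day boundaries.
    """
    n_bouts = int(rng.integers(1, max_bouts + 1))
    total = int(rng.integers(n_bouts, 1441))
    # random composition of `total` into n_bouts positive parts
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_bouts - 1, replace=False)) if n_bouts > 1 else np.array([], dtype=int)
    durations = np.diff(np.concatenate(([0], cuts, [total])))
    kinds = rng.choice(
        list(_KIND_WEIGHTS), size=n_bouts, p=list(_KIND_WEIGHTS.values())
    )
    return EpochDayPlan(
        subject_id=subject_id,
        date=date,
        bouts=tuple(zip(durations.tolist(), kinds.tolist())),
        epoch_s=epoch_s,
        seed=int(rng.integers(2**31)),
    )


def load_daily_cohort_config(path) -> DailyCohortConfig:
    """Load a :class:`DailyCohortConfig` from a flat YAML mapping."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return DailyCohortConfig(**raw)
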