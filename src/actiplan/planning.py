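"""Measurement-protocol planners: SEM surfaces, Spearman-Brown days,
habitual-level days.

Three formulas drive protocol design for a study measuring a daily
outcome on ``n`` subjects over ``m`` repeated days, given a
between-subject variance ``sigma_b2`` and within-subject variance
``sigma_w2``:

- the standard error of the group mean,
  ``SEM(n, m) = sqrt(sigma_b2/n + sigma_w2/(m*n))`` — within-subject
  noise is averaged down by both ``n`` and ``m``, but between-subject
  variation only by ``n``, which is why doubling subjects always beats
  doubling days;
- the Spearman-Brown prophecy,
  ``D = ICC_d (1 - ICC_o) / (ICC_o (1 - ICC_d))`` — the number of
  repeated days needed to raise an observed single-day reliability
  ``ICC_o`` to a desired ranking reliability ``ICC_d``;
- the habitual-level planner, ``D = (z * CV_w / d0)^2`` — days needed
  so an individual's observed mean falls within a fraction ``d0`` of
  their true habitual level with the coverage implied by the normal
  deviate ``z`` (1.96 for 95%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .variance import VarianceComponents

#: Default planning grids, covering the ranges a desk study of 10-500
#: subjects over up to four weeks would explore.
DEFAULT_N_GRID = tuple(range(10, 501, 10))
DEFAULT_M_GRID = tuple(range(1, 29))


def _components_pair(components) -> tuple[float, float]:
    if isinstance(components, VarianceComponents):
        return components.sigma_b2, components.sigma_w2
    sigma_b2, sigma_w2 = components
    return float(sigma_b2), float(sigma_w2)


def sem(n, m, components) -> float | np.ndarray:
    """Standard error of the group mean for n subjects on m days each.

    ``components`` is a :class:`VarianceComponents` or a
    ``(sigma_b2, sigma_w2)`` pair.  Vectorised over ``n`` and ``m``.
    """
    sigma_b2, sigma_w2 = _components_pair(components)
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(n < 1) or np.any(m < 1):
        raise DomainError("n and m must be at least 1")
    out = np.sqrt(sigma_b2 / n + sigma_w2 / (m * n))
    return float(out) if out.ndim == 0 else out


def relative_sem(sem_value, grand_mean: float):
    """SEM as a percentage of the mean."""
    if grand_mean <= 0:
        raise DomainError("relative SEM requires a positive mean")
    return 100.0 * np.asarray(sem_value, dtype=float) / grand_mean if np.ndim(
        sem_value
    ) else 100.0 * float(sem_value) / grand_mean


@dataclass(frozen=True)
class SEMSurface:
    """SEM and relative SEM over an (n subjects x m days) grid."""

    n_grid: np.ndarray
    m_grid: np.ndarray
    sem: np.ndarray  # shape (len(n_grid), len(m_grid)), outcome units
    relative_sem: np.ndarray  # same shape, percent
    sigma_b2: float
    sigma_w2: float
    grand_mean: float

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (n, m) with sem and relative_sem."""
        nn, mm = np.meshgrid(self.n_grid, self.m_grid, indexing="ij")
        return pd.DataFrame(
            {
                "n": nn.ravel().astype(int),
                "m": mm.ravel().astype(int),
                "sem": self.sem.ravel(),
                "relative_sem": self.relative_sem.ravel(),
            }
        )

    def at(self, n: int, m: int) -> tuple[float, float]:
        i = int(np.flatnonzero(self.n_grid == n)[0])
        j = int(np.flatnonzero(self.m_grid == m)[0])
        return float(self.sem[i, j]), float(self.relative_sem[i, j])


def sem_surface(
    components,
    grand_mean: float,
    n_grid=DEFAULT_N_GRID,
    m_grid=DEFAULT_M_GRID,
) -> SEMSurface:
    """Evaluate the SEM over every (n, m) combination of the grids."""
    n_grid = np.asarray(sorted(set(int(n) for n in n_grid)))
    m_grid = np.asarray(sorted(set(int(m) for m in m_grid)))
    if n_grid.size == 0 or m_grid.size == 0:
        raise DomainError("grids must be non-empty")
    if n_grid[0] < 1 or m_grid[0] < 1:
        raise DomainError("grid values must be positive")
    sigma_b2, sigma_w2 = _components_pair(components)
    values = sem(n_grid[:, None], m_grid[None, :], (sigma_b2, sigma_w2))
    return SEMSurface(
        n_grid=n_grid,
        m_grid=m_grid,
        sem=values,
        relative_sem=relative_sem(values, grand_mean),
        sigma_b2=sigma_b2,
        sigma_w2=sigma_w2,
        grand_mean=grand_mean,
    )


def required_n(
    target_relative_sem: float, m: int, components, grand_mean: float
) -> int:
    """Smallest n whose relative SEM at m days is at or below the target.

    Closed form: relative SEM <= t  iff
    n >= (sigma_b2 + sigma_w2/m) * (100 / (t * mean))^2.
    """
    if target_relative_sem <= 0:
        raise DomainError("target relative SEM must be positive")
    if grand_mean <= 0:
        raise DomainError("relative SEM requires a positive mean")
    if m < 1:
        raise DomainError("m must be at least 1")
    sigma_b2, sigma_w2 = _components_pair(components)
    bound = (sigma_b2 + sigma_w2 / m) * (100.0 / (target_relative_sem * grand_mean)) ** 2
    n = max(1, math.ceil(bound - 1e-12))
    # guard against floating-point edge cases at the boundary
    while relative_sem(sem(n, m, (sigma_b2, sigma_w2)), grand_mean) > target_relative_sem:
        n += 1
    return n


def spearman_brown_days(
    icc_observed: float, icc_desired: float, *, ceil: bool = False
) -> float:
    """Repeated days needed to reach a desired ranking reliability.

    ``D = ICC_d (1 - ICC_o) / (ICC_o (1 - ICC_d))``.  The raw (possibly
    fractional, possibly sub-1) value is returned; ``ceil=True`` rounds
    up since a monitoring day is indivisible.
    """
    for name, v in (("icc_observed", icc_observed), ("icc_desired", icc_desired)):
        if not 0 < v < 1:
            raise DomainError(f"{name} must lie strictly in (0, 1), got {v}")
    d = icc_desired * (1 - icc_observed) / (icc_observed * (1 - icc_desired))
    return float(math.ceil(d)) if ceil else float(d)


def habitual_days(
    z_alpha: float, cv_w: float, d0: float, *, ceil: bool = False
) -> float:
    """Days needed to pin an individual's habitual level.

    ``D = (z_alpha * cv_w / d0)^2``: with ``D`` monitored days the
    observed mean falls within a fraction ``d0`` of the true habitual
    level for the share of individuals implied by ``z_alpha`` (1.96
    gives 95%).  ``cv_w`` is the within-subject CV as a fraction.
    """
    if z_alpha <= 0:
        raise DomainError("z_alpha must be positive")
    if cv_w < 0:
        raise DomainError("cv_w must be non-negative")
    if d0 <= 0:
        raise DomainError("d0 must be positive")
    d = (z_alpha * cv_w / d0) ** 2
    return float(math.ceil(d)) if ceil else float(d)


def plot_surface(surface: SEMSurface, *, relative: bool = True, ax=None):
    """Static heat-map of a SEM surface (days x subjects)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    z = surface.relative_sem if relative else surface.sem
    im = ax.imshow(
        z.T,
        origin="lower",
        aspect="auto",
        extent=(
            surface.n_grid[0],
            surface.n_grid[-1],
            surface.m_grid[0],
            surface.m_grid[-1],
        ),
    )
    ax.set_xlabel("subjects (n)")
    ax.set_ylabel("repeated days (m)")
    label = "relative SEM (%)" if relative else "SEM"
    ax.figure.colorbar(im, ax=ax, label=label)
    return ax
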