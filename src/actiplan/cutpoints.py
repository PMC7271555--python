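"""Intensity classification of 60-s accelerometer epochs.

Intensity bands are defined on counts per minute (cpm) of the vertical
axis.  The default scheme is the widely used adult cut-points:
sedentary below 100 cpm, light 100-1951 cpm, moderate 1952-5723 cpm,
vigorous 5724 cpm and above.  Bands are contiguous, half-open
``[low, high)`` intervals covering ``[0, inf)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidConfigError

#: Canonical band order used everywhere in the package.
BANDS = ("sedentary", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class CutPointScheme:
    """Contiguous cpm intensity bands.

    Parameters
    ----------
    light_min, moderate_min, vigorous_min
        Inclusive lower cpm bounds of the light, moderate and vigorous
        bands.  Sedentary is everything in ``[0, light_min)``; vigorous
        is unbounded above.
    name
        Free-text label carried into provenance output.
    """

    light_min: float = 100.0
    moderate_min: float = 1952.0
    vigorous_min: float = 5724.0
    name: str = "freedson_adult"

    def __post_init__(self) -> None:
        if not (0 < self.light_min < self.moderate_min < self.vigorous_min):
            raise InvalidConfigError(
                "cut-points must satisfy 0 < light < moderate < vigorous, got "
                f"{self.light_min}, {self.moderate_min}, {self.vigorous_min}"
            )

    @property
    def edges(self) -> np.ndarray:
        """Band edges: ``[0, light_min, moderate_min, vigorous_min, inf)``."""
        return np.array(
            [0.0, self.light_min, self.moderate_min, self.vigorous_min, np.inf]
        )

    def band_interval(self, band: str) -> tuple[float, float]:
        """Half-open ``[low, high)`` cpm interval of a named band."""
        i = BANDS.index(band)
        e = self.edges
        return float(e[i]), float(e[i + 1])

    def classify(self, cpm: np.ndarray) -> np.ndarray:
        """Map cpm values to band indices 0..3 (order of :data:`BANDS`)."""
        cpm = np.asarray(cpm, dtype=float)
        if np.any(cpm < 0):
            raise InvalidConfigError("cpm values must be non-negative")
        # searchsorted on the inner edges gives the half-open band index
        return np.searchsorted(self.edges[1:-1], cpm, side="right")


#: Default scheme used throughout unless the caller overrides it.
FREEDSON_ADULT = CutPointScheme()
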