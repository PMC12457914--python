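"""Growing-degree-day (GDD) accumulation.

Daily heat units above a crop-specific base temperature, accumulated from
full bloom, anchor the critical time points of nut development (kernel-fill
completion near 1800 GDD, hull softening / shell split near 2100 GDD,
commercial harvest near 2500 GDD for 'Golden Hills' pistachio).  The base
temperature for pistachio is 7 degrees C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TemperatureSeries:
    """Per-day maximum/minimum temperatures (degrees C) and the base temperature."""

    t_max: np.ndarray
    t_min: np.ndarray
    t_base: float = 7.0

    def __post_init__(self) -> None:
        self.t_max = np.asarray(self.t_max, dtype=np.float64)
        self.t_min = np.asarray(self.t_min, dtype=np.float64)
        if self.t_max.shape != self.t_min.shape:
            raise ValueError("t_max and t_min must be the same length")
        bad = np.nonzero(self.t_max < self.t_min)[0]
        if len(bad):
            raise ValueError(f"t_max < t_min on day(s) {(bad + 1).tolist()}")

    @classmethod
    def from_csv(cls, path, t_base: float = 7.0) -> "TemperatureSeries":
        df = pd.read_csv(path)
        return cls(df["tmax"].to_numpy(), df["tmin"].to_numpy(), t_base=t_base)


def gdd_accumulate(series: TemperatureSeries) -> np.ndarray:
    """Cumulative GDD per day: sum of max((Tmax + Tmin)/2 - Tbase, 0).

    Days whose mean temperature falls below the base contribute nothing,
    so the accumulation is non-decreasing.  The caller chooses the start
    day (accumulation conventionally begins at full bloom).
    """
    if len(series.t_max) == 0:
        raise ValueError("empty temperature series")
    daily = np.maximum((series.t_max + series.t_min) / 2.0 - series.t_base, 0.0)
    return np.cumsum(daily)
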