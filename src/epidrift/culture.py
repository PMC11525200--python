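"""Scalar statistics for competition and culture assays.

Covers the readouts of mixed-population competition experiments (relative
fitness of a focal subpopulation), flow-cytometry stratification (ratio of
suprabasal to basal cells), epithelial barrier permeability (tracer
fluorescence leakage), excisional wound closure, and the fold-expansion
arithmetic of punch passaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "CompetitionSeries",
    "PermeabilityResult",
    "WoundClosure",
    "relative_fitness",
    "log_relative_fitness",
    "stratification_ratio",
    "permeability_percent",
    "wound_closure_rate",
    "expansion_projection",
    "harvest_fold",
    "round_sig",
]


@dataclass
class CompetitionSeries:
    """Proportion of a focal subpopulation in a mixed culture over time."""

    times: np.ndarray
    proportion: np.ndarray
    focal_label: str = "focal"
    n_cells_sampled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.proportion = np.asarray(self.proportion, dtype=float)
        if self.times.size != self.proportion.size or self.times.size == 0:
            raise ValueError("times and proportion must be nonempty and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.proportion <= 0) or np.any(self.proportion > 1):
            raise ValueError("proportions must be in (0, 1]")


def relative_fitness(series: CompetitionSeries, t: float) -> float:
    """Fold change of the focal proportion at ``t`` versus the initial time.

    1.0 means neutral competition; values above 1 indicate the focal
    population is outcompeting its neighbor.
    """
    idx = np.flatnonzero(np.isclose(series.times, t))
    if idx.size == 0:
        raise ValueError(f"time {t} not present in series")
    p0 = series.proportion[0]
    if p0 == 0:
        raise ZeroDivisionError("initial proportion is zero; fitness undefined")
    return float(series.proportion[idx[0]] / p0)


def log_relative_fitness(series: CompetitionSeries, t: float) -> float:
    """Natural-log variant of :func:`relative_fitness` (convenience)."""
    return math.log(relative_fitness(series, t))


def stratification_ratio(n_suprabasal: float, n_basal: float) -> float:
    """Suprabasal / basal cell-count ratio (ITGA6- over ITGA6+ by cytometry)."""
    if n_basal <= 0:
        raise ValueError("basal cell count must be positive")
    if n_suprabasal < 0:
        raise ValueError("suprabasal cell count must be >= 0")
    return float(n_suprabasal) / float(n_basal)


class PermeabilityResult(NamedTuple):
    percent: float
    out_of_range: bool


def permeability_percent(
    f_sample: float, f_blank: float, f_max: float
) -> PermeabilityResult:
    """Barrier permeability as percent of the no-cell (100%) tracer control.

    ``100 * (f_sample - f_blank) / (f_max - f_blank)``.  Noisy inputs may
    fall outside [0, 100]; the value is returned unclipped with a flag so
    that assay noise remains visible.
    """
    if f_max <= f_blank:
        raise ValueError("f_max must exceed f_blank")
    pct = 100.0 * (f_sample - f_blank) / (f_max - f_blank)
    return PermeabilityResult(float(pct), not 0.0 <= pct <= 100.0)


class WoundClosure(NamedTuple):
    days: np.ndarray
    fraction_closed: np.ndarray
    rate_per_day: float


def wound_closure_rate(areas: dict[float, float]) -> WoundClosure:
    """Fraction of the wound closed per day and its least-squares daily rate.

    ``fraction_closed(d) = (A(0) - A(d)) / A(0)``; the overall rate is the
    slope of the ordinary least-squares line (with intercept) of
    fraction_closed against day.
    """
    days = np.array(sorted(areas), dtype=float)
    a = np.array([areas[d] for d in days], dtype=float)
    if np.any(a < 0):
        raise ValueError("wound areas must be >= 0")
    if days[0] != 0:
        raise ValueError("day-0 area required")
    if a[0] <= 0:
        raise ValueError("day-0 wound area must be positive")
    frac = (a[0] - a) / a[0]
    slope = float(np.polyfit(days, frac, 1)[0]) if days.size > 1 else 0.0
    return WoundClosure(days, frac, slope)


def expansion_projection(
    initial_fold: float, split_factor: int, rounds: int
) -> float:
    """Projected expansion after serial punch passaging.

    One culture yields ``initial_fold`` times the input cells; each passage
    splits the membrane into ``split_factor`` pieces that each regrow to
    confluence, so ``rounds`` passages multiply the projection by
    ``split_factor ** rounds``.
    """
    if initial_fold <= 0:
        raise ValueError("initial_fold must be positive")
    if split_factor < 1 or int(split_factor) != split_factor:
        raise ValueError("split_factor must be an integer >= 1")
    if rounds < 0 or int(rounds) != rounds:
        raise ValueError("rounds must be a nonnegative integer")
    return float(initial_fold) * float(split_factor) ** int(rounds)


def harvest_fold(harvested_cells: float, initial_cells: float) -> float:
    """Cell-number amplification of one culture: harvested / initial."""
    if initial_cells <= 0:
        raise ValueError("initial cell count must be positive")
    if harvested_cells < 0:
        raise ValueError("harvested cell count must be >= 0")
    return float(harvested_cells) / float(initial_cells)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (headline-style reporting)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")
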