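"""Trajectory analysis of tracked single-colored areas (SCA).

SCA recognizable at week 4 of imaging are followed weekly until week 19, or
until they shrink below the imaging detection limit (recorded as area 0).
Each trajectory is summarized by its mean area over three windows --
weeks 4-8 (A4_8), weeks 10-13 (A10_13) and weeks 15-19 (A15_19) -- and
classified by the window ordering:

========  =============================================
Decay1    A10_13 = 0 and A15_19 = 0
Decay2    A10_13 > 0 and A15_19 = 0
Decay3    otherwise, A4_8 > A10_13 > A15_19
Biphasic  A4_8 < A10_13 > A15_19
Growing   A4_8 < A10_13 < A15_19
Steady    everything else (ties and mixed patterns)
========  =============================================

Rules are applied in the listed order; equalities fall through to the
Steady catch-all.  The module also builds per-week cohort summary curves
(mean surviving area, surviving count, total labeled area) and wraps the
matched-pairs Wilcoxon signed-rank comparison between weeks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .sp_model import DriftCurve

__all__ = [
    "SCATrajectory",
    "TrajectoryClass",
    "CohortSummary",
    "IneligibleTrajectoryError",
    "window_means",
    "classify_trajectory",
    "classify_cohort",
    "cohort_summary",
    "paired_signed_rank",
    "trajectories_from_frame",
    "trajectories_to_frame",
]

WINDOWS = {"A4_8": range(4, 9), "A10_13": range(10, 14), "A15_19": range(15, 20)}
OBSERVATION_WEEKS = range(4, 20)


class IneligibleTrajectoryError(ValueError):
    """Trajectory lacks observations in a classification window."""


class TrajectoryClass(str, Enum):
    DECAY1 = "Decay1"
    DECAY2 = "Decay2"
    DECAY3 = "Decay3"
    BIPHASIC = "Biphasic"
    GROWING = "Growing"
    STEADY = "Steady"


@dataclass
class SCATrajectory:
    """Weekly measured areas of one SCA; 0 means below detection."""

    sca_id: str
    culture_id: str
    areas: dict[int, float]

    def __post_init__(self) -> None:
        for week, area in self.areas.items():
            if area < 0:
                raise ValueError(f"negative area at week {week} for {self.sca_id}")


@dataclass
class CohortSummary:
    """Cohort-level output: summary curves and/or class composition."""

    curve: DriftCurve | None = None
    class_counts: dict[TrajectoryClass, int] | None = None
    class_proportions: dict[TrajectoryClass, float] | None = None
    n_eligible: int = 0
    ineligible_ids: list[str] = field(default_factory=list)


def window_means(traj: SCATrajectory) -> tuple[float, float, float]:
    """Mean of available weekly areas in each classification window."""
    out = []
    for name, weeks in WINDOWS.items():
        vals = [traj.areas[w] for w in weeks if w in traj.areas]
        if not vals:
            raise IneligibleTrajectoryError(
                f"{traj.sca_id}: no observations in window {name}"
            )
        out.append(float(np.mean(vals)))
    return tuple(out)


def _classify(a48: float, a1013: float, a1519: float) -> TrajectoryClass:
    if a1013 == 0 and a1519 == 0:
        return TrajectoryClass.DECAY1
    if a1013 > 0 and a1519 == 0:
        return TrajectoryClass.DECAY2
    if a48 > a1013 > a1519:
        return TrajectoryClass.DECAY3
    if a48 < a1013 > a1519:
        return TrajectoryClass.BIPHASIC
    if a48 < a1013 < a1519:
        return TrajectoryClass.GROWING
    return TrajectoryClass.STEADY


def classify_trajectory(traj: SCATrajectory) -> TrajectoryClass:
    """Classify one trajectory from its window means (rules above, in order)."""
    return _classify(*window_means(traj))


def classify_cohort(trajs: list[SCATrajectory]) -> CohortSummary:
    """Class counts and proportions over a cohort.

    Trajectories without observations in every window are reported in
    ``ineligible_ids`` and excluded from the denominators.
    """
    if not trajs:
        raise ValueError("empty cohort")
    counts = {cls: 0 for cls in TrajectoryClass}
    ineligible: list[str] = []
    for traj in trajs:
        try:
            counts[classify_trajectory(traj)] += 1
        except IneligibleTrajectoryError:
            ineligible.append(traj.sca_id)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no eligible trajectory in cohort")
    props = {cls: c / n for cls, c in counts.items()}
    return CohortSummary(
        class_counts=counts,
        class_proportions=props,
        n_eligible=n,
        ineligible_ids=ineligible,
    )


def cohort_summary(
    trajs: list[SCATrajectory], detection_threshold: float = 0.0
) -> CohortSummary:
    """Per-week mean surviving area, surviving count and total labeled area.

    A trajectory survives at a week if its recorded area exceeds the
    threshold (default 0: any positive area, the detection limit having been
    applied upstream as recorded zeros).  Weeks with no survivor get a
    missing (NaN) mean, count 0 and total 0.
    """
    if not trajs:
        raise ValueError("empty cohort")
    weeks = sorted({w for traj in trajs for w in traj.areas})
    counts, means, totals = [], [], []
    for w in weeks:
        areas = np.array(
            [traj.areas[w] for traj in trajs if w in traj.areas], dtype=float
        )
        alive = areas[areas > detection_threshold]
        counts.append(alive.size)
        means.append(alive.mean() if alive.size else np.nan)
        totals.append(alive.sum())
    curve = DriftCurve(
        times=np.asarray(weeks, dtype=float),
        mean_area=np.asarray(means),
        count=np.asarray(counts, dtype=float),
        total_area=np.asarray(totals),
    )
    return CohortSummary(curve=curve, n_eligible=len(trajs))


def paired_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Pairs with zero difference are dropped; the exact null distribution is
    used for n <= 25 and the normal approximation with continuity correction
    beyond.  If every difference is zero the test is degenerate and (0.0,
    1.0) is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    diffs = x - y
    nonzero = np.count_nonzero(diffs)
    if nonzero == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return 0.0, 1.0
    if nonzero < 3:
        raise ValueError("need >= 3 nonzero paired differences")
    method = "exact" if nonzero <= 25 else "approx"
    res = stats.wilcoxon(
        x,
        y,
        zero_method="wilcox",
        alternative="two-sided",
        correction=(method == "approx"),
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def trajectories_from_frame(frame: pd.DataFrame) -> list[SCATrajectory]:
    """Build trajectories from a long-format table
    (columns sca_id, culture_id, week, area_mm2)."""
    trajs = []
    for (sca_id, culture_id), grp in frame.groupby(["sca_id", "culture_id"], sort=True):
        areas = dict(zip(grp["week"].astype(int), grp["area_mm2"].astype(float)))
        trajs.append(SCATrajectory(str(sca_id), str(culture_id), areas))
    return trajs


def trajectories_to_frame(trajs: list[SCATrajectory]) -> pd.DataFrame:
    rows = [
        (traj.sca_id, traj.culture_id, week, traj.areas[week])
        for traj in trajs
        for week in sorted(traj.areas)
    ]
    return pd.DataFrame(rows, columns=["sca_id", "culture_id", "week", "area_mm2"])
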