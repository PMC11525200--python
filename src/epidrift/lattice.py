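"""Stochastic lattice simulation of multicolor clonal labeling.

A confluent basal layer is modeled as a fully occupied rectangular lattice,
one progenitor per site.  Division is coupled to stratification: at total
rate ``N * lambda`` a cell is chosen uniformly to divide, a second cell is
chosen to leave the basal layer (stratify), and the daughter takes the
vacated site, inheriting the mother's heritable color label.  Site occupancy
is therefore conserved at every instant, and because the displaced cell is
chosen without regard to label, the dynamics are neutral: the labeled
fraction of each color is a martingale while same-color patches coarsen.

Two displacement rules are provided:

* ``neighbor`` -- the stratifying cell is one of the divider's von Neumann
  neighbors (a voter-model rule; spatial coarsening of single-colored
  areas, SCA);
* ``mean_field`` -- the stratifying cell is drawn uniformly from the whole
  lattice (Moran-type), which reduces to the well-mixed critical
  birth--death process while clone sizes are much smaller than the lattice,
  enabling exact comparison with the analytic model.

The event loop is JIT-compiled with numba when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .sp_model import DriftCurve, DriftParams

__all__ = [
    "LatticeConfig",
    "SimTrace",
    "run_lattice",
    "label_components",
    "trace_to_summary",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Configuration of a lattice labeling simulation.

    ``colors`` counts label colors (plus the implicit unlabeled state 0).
    ``labeled_fraction`` is the probability that a site carries a label at
    t=0, each labeled site drawing its color uniformly.  ``area_per_cell``
    defaults to ``1 / params.rho`` when the density is set, else 1 mm^2 per
    site.
    """

    width: int
    height: int
    params: DriftParams
    colors: int = 4
    labeled_fraction: float = 1.0
    boundary: str = "periodic"
    mode: str = "neighbor"
    duration: float = 10.0
    sample_interval: float = 1.0
    area_per_cell: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width * self.height < 4:
            raise ValueError("lattice must have at least 4 sites")
        if not 0 <= self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if self.duration <= 0 or self.sample_interval <= 0:
            raise ValueError("duration and sample_interval must be positive")
        if self.colors < 1:
            raise ValueError("need at least one label color")
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.mode not in ("neighbor", "mean_field"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.area_per_cell is not None and self.area_per_cell <= 0:
            raise ValueError("area_per_cell must be positive")
        if self.params.lambda_div is None:
            raise ValueError("LatticeConfig requires params.lambda_div")

    @property
    def cell_area(self) -> float:
        if self.area_per_cell is not None:
            return self.area_per_cell
        if self.params.rho is not None:
            return 1.0 / self.params.rho
        return 1.0


@dataclass
class SimTrace:
    """Sampled output of a lattice run.

    ``sca_records[i]`` lists ``(color, area_mm2, component_id)`` for every
    single-colored connected area at ``sample_times[i]``; ``label_fraction``
    has shape ``(n_samples, colors)``.
    """

    sample_times: np.ndarray
    sca_records: list[list[tuple[int, float, int]]]
    label_fraction: np.ndarray
    config: LatticeConfig | None = None
    grids: list[np.ndarray] = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, color, cid, area)
            for t, recs in zip(self.sample_times, self.sca_records)
            for color, area, cid in recs
        ]
        return pd.DataFrame(rows, columns=["time_weeks", "color", "component_id", "area_mm2"])


def _neighbor_events_python(grid, src, u, width, height, periodic):
    for i in range(src.shape[0]):
        s = src[i]
        x = s % width
        y = s // width
        if periodic:
            d = int(u[i] * 4)
            if d == 0:
                nx, ny = (x + 1) % width, y
            elif d == 1:
                nx, ny = (x - 1) % width, y
            elif d == 2:
                nx, ny = x, (y + 1) % height
            else:
                nx, ny = x, (y - 1) % height
        else:
            # choose uniformly among in-bounds von Neumann neighbors
            nval = 0
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if 0 <= x + dx < width and 0 <= y + dy < height:
                    nval += 1
            pick = int(u[i] * nval)
            j = -1
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if 0 <= x + dx < width and 0 <= y + dy < height:
                    j += 1
                    if j == pick:
                        nx, ny = x + dx, y + dy
                        break
        grid[ny * width + nx] = grid[s]


def _mean_field_events_python(grid, src, u, n_sites):
    for i in range(src.shape[0]):
        grid[int(u[i] * n_sites)] = grid[src[i]]


try:  # optional acceleration
    from numba import njit

    _neighbor_events = njit(cache=True)(_neighbor_events_python)
    _mean_field_events = njit(cache=True)(_mean_field_events_python)
except ImportError:  # pragma: no cover
    _neighbor_events = _neighbor_events_python
    _mean_field_events = _mean_field_events_python


def run_lattice(config: LatticeConfig) -> SimTrace:
    """Run the division--stratification process and sample the color field.

    Events arrive as a Poisson process at rate ``N * lambda`` (exponential
    interarrival times); the grid is sampled every ``sample_interval`` weeks
    starting at t=0.  Identical seed implies an identical trace.
    """
    rng = np.random.default_rng(config.seed)
    n_sites = config.width * config.height
    lam = config.params.lambda_div
    grid = np.zeros(n_sites, dtype=np.int32)
    labeled = rng.random(n_sites) < config.labeled_fraction
    grid[labeled] = rng.integers(1, config.colors + 1, size=int(labeled.sum()))

    n_samples = int(np.floor(config.duration / config.sample_interval)) + 1
    sample_times = np.arange(n_samples) * config.sample_interval
    periodic = config.boundary == "periodic"
    area = config.cell_area

    sca_records: list[list[tuple[int, float, int]]] = []
    label_fraction = np.zeros((n_samples, config.colors))
    grids: list[np.ndarray] = []
    total_rate = n_sites * lam
    for i, _t in enumerate(sample_times):
        if i > 0 and total_rate > 0:
            n_events = rng.poisson(total_rate * config.sample_interval)
            # process in chunks to bound memory on long intervals
            for start in range(0, n_events, 1_000_000):
                m = min(1_000_000, n_events - start)
                src = rng.integers(0, n_sites, size=m)
                u = rng.random(m)
                if config.mode == "neighbor":
                    _neighbor_events(grid, src, u, config.width, config.height, periodic)
                else:
                    _mean_field_events(grid, src, u, n_sites)
        assert grid.size == n_sites  # occupancy conservation
        field2d = grid.reshape(config.height, config.width)
        comps = label_components(field2d, connectivity=4, area_per_cell=area)
        sca_records.append(comps)
        for c in range(1, config.colors + 1):
            label_fraction[i, c - 1] = np.count_nonzero(grid == c) / n_sites
        grids.append(field2d.copy())
    return SimTrace(
        sample_times=sample_times,
        sca_records=sca_records,
        label_fraction=label_fraction,
        config=config,
        grids=grids,
    )


_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


def label_components(
    grid: np.ndarray, connectivity: int = 4, area_per_cell: float = 1.0
) -> list[tuple[int, float, int]]:
    """Connected components of identically colored labeled sites.

    A single-colored area (SCA) is a maximal connected region of one label
    color; unlabeled sites (0) are background.  Returns
    ``(color, area_mm2, component_id)`` triples with ids unique within the
    call.  Components do not wrap across lattice boundaries.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT4 if connectivity == 4 else _STRUCT8
    out: list[tuple[int, float, int]] = []
    next_id = 0
    for color in np.unique(grid):
        if color == 0:
            continue
        labels, n = ndimage.label(grid == color, structure=struct)
        counts = np.bincount(labels.ravel())[1:]
        for k in range(n):
            out.append((int(color), float(counts[k]) * area_per_cell, next_id))
            next_id += 1
    return out


def trace_to_summary(trace: SimTrace, detection_threshold: float = 0.0) -> DriftCurve:
    """Reduce a trace to per-time mean SCA area, SCA count and total area.

    Components smaller than ``detection_threshold`` are indistinguishable
    from background and contribute nothing; times with no detectable SCA get
    count 0, total 0 and a missing (NaN) mean.
    """
    if detection_threshold < 0:
        raise ValueError("detection threshold must be >= 0")
    if len(trace.sca_records) == 0:
        raise ValueError("empty trace")
    counts, means, totals = [], [], []
    for recs in trace.sca_records:
        areas = np.array([a for _c, a, _i in recs], dtype=float)
        areas = areas[areas >= detection_threshold] if detection_threshold > 0 else areas
        counts.append(areas.size)
        means.append(areas.mean() if areas.size else np.nan)
        totals.append(areas.sum())
    return DriftCurve(
        times=np.asarray(trace.sample_times, dtype=float),
        mean_area=np.asarray(means),
        count=np.asarray(counts, dtype=float),
        total_area=np.asarray(totals),
    )
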