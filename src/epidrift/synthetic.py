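"""Seeded synthetic-data generators for every analysis stage.

Each generator is a pure function of its configuration (including the
seed), producing tables with the statistical structure the corresponding
analysis assumes:

* multicolor lineage-tracing cohorts -- clones evolving by the critical
  birth--death process, measured with multiplicative lognormal imaging
  noise and an area detection floor (below which a 0 is recorded);
* two-population competition series -- replicator (logistic) dynamics with
  selection coefficient ``s`` per week, read out by binomial cell sampling;
* pooled-screen guide counts -- Dirichlet-uniform initial library
  composition, exponential selection over the experiment attenuated by the
  fraction of cells actually gene-targeted, and negative-binomial
  sequencing counts per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .culture import CompetitionSeries
from .sca import SCATrajectory
from .screen import GuideTable
from .sp_model import simulate_critical_birth_death

__all__ = [
    "ConfettiCohortConfig",
    "CompetitionConfig",
    "ScreenConfig",
    "gen_confetti_trajectories",
    "gen_competition_series",
    "gen_screen_counts",
    "expected_screen_log2fc",
]


@dataclass(frozen=True)
class ConfettiCohortConfig:
    """Multicolor lineage-tracing cohort at the scale of the tracked study:
    9 cultures x 39 SCA = 351 clones imaged weekly from week 4 to week 19.

    ``rho`` converts model cells to areas (area per cell = 1/rho).  The
    model cell is a coarse-grained *detectable* clonal unit: with the
    defaults one unit (0.02 mm^2) lies above the imaging detection floor
    (0.01 mm^2), matching a cohort defined by clones recognizable at the
    first imaging week.  Tracking starts at week 4, so initial sizes are
    drawn from the surviving-clone (geometric) distribution at week 4 after
    labeling at week 0.
    """

    n_cultures: int = 9
    sca_per_culture: int = 39
    kappa: float = 0.25
    weeks: tuple[int, ...] = tuple(range(4, 20))
    area_noise_cv: float = 0.1
    detection_threshold: float = 0.01
    rho: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cultures, self.sca_per_culture) < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.kappa <= 0 or self.rho <= 0:
            raise ValueError("kappa and rho must be positive")
        if self.area_noise_cv < 0 or self.detection_threshold < 0:
            raise ValueError("noise and threshold must be >= 0")
        if not all(4 <= w <= 19 for w in self.weeks):
            raise ValueError("observation weeks must lie in 4..19")


def gen_confetti_trajectories(config: ConfettiCohortConfig) -> list[SCATrajectory]:
    """Generate a seeded cohort of SCA trajectories under neutral drift.

    Week-4 sizes ~ geometric with survival parameter ``1/(1 + 4 kappa)``
    (the conditional clone-size law of the critical process); sizes then
    evolve by Gillespie from week 4 to the last observation week.  Measured
    area = cells / rho x lognormal(CV) noise; areas below the detection
    threshold are recorded as 0.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_cultures * config.sca_per_culture
    weeks = np.asarray(sorted(config.weeks))
    t_first = float(weeks[0])
    p_geom = 1.0 / (1.0 + config.kappa * t_first)
    n_init = rng.geometric(p_geom, size=n_total)
    t_eval = weeks.astype(float) - t_first
    later = t_eval > 0
    sizes = np.empty((n_total, weeks.size), dtype=np.int64)
    sizes[:, 0] = n_init
    if later.any():
        sizes[:, later] = simulate_critical_birth_death(
            config.kappa, t_eval[later], n_total, rng=rng, n0=n_init
        )
    true_area = sizes / config.rho
    if config.area_noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.area_noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=true_area.shape)
    else:
        noise = 1.0
    measured = true_area * noise
    measured[measured < config.detection_threshold] = 0.0
    trajs = []
    for i in range(n_total):
        culture = f"culture{i // config.sca_per_culture + 1:02d}"
        areas = {int(w): float(measured[i, j]) for j, w in enumerate(weeks)}
        trajs.append(SCATrajectory(f"sca{i + 1:04d}", culture, areas))
    return trajs


@dataclass(frozen=True)
class CompetitionConfig:
    """Two-population competition with selection coefficient ``s`` per week.

    ``s = 0`` is neutral (the focal proportion is a martingale);
    ``n_cells_sampled = None`` disables sampling noise.
    """

    p0: float = 0.5
    s: float = 0.0
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 11))
    n_cells_sampled: int | None = 10_000
    focal_label: str = "focal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")
        if len(self.times) < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing with >= 2 points")
        if self.n_cells_sampled is not None and self.n_cells_sampled < 1:
            raise ValueError("n_cells_sampled must be positive")


def competition_true_proportion(config: CompetitionConfig, t) -> np.ndarray:
    """Replicator closed form ``p(t) = p0 e^{st} / (1 - p0 + p0 e^{st})``."""
    t = np.asarray(t, dtype=float)
    w = config.p0 * np.exp(config.s * t)
    return w / (1.0 - config.p0 + w)


def gen_competition_series(config: CompetitionConfig) -> CompetitionSeries:
    """Generate a seeded competition proportion series with binomial sampling."""
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    p_true = competition_true_proportion(config, times)
    if config.n_cells_sampled is None:
        observed = p_true
        n = None
    else:
        n = np.full(times.size, config.n_cells_sampled)
        draws = rng.binomial(n, p_true)
        # keep proportions inside (0, 1]: an observed 0 would make downstream
        # fold changes undefined, so floor at half a cell
        observed = np.maximum(draws, 0.5) / n
    return CompetitionSeries(
        times=times,
        proportion=observed,
        focal_label=config.focal_label,
        n_cells_sampled=n,
    )


@dataclass(frozen=True)
class ScreenConfig:
    """Pooled fitness screen: 23 driver + 62 candidate + 50 essential genes
    plus a large nontargeting control block, 3 replicates, weeks 0 and 3.

    ``fitness`` maps gene -> selection coefficient per week (unlisted genes
    are neutral).  ``targeted_fraction`` attenuates selection (only that
    fraction of cells carries an edit; the rest of the culture is
    effectively wild type), entering the expected growth as
    ``exp(duration * s * (1 - targeted_fraction))``.  ``depth`` is the mean
    sequencing depth per guide; ``depth=None`` returns expected fractional
    counts (noiseless validation mode).  ``dispersion`` is the
    negative-binomial overdispersion alpha (0 = Poisson).
    """

    n_drivers: int = 23
    n_candidates: int = 62
    n_essential: int = 50
    guides_per_gene: int = 4
    n_nt_guides: int = 800
    fitness: dict = field(default_factory=dict)
    targeted_fraction: float = 0.13
    duration: float = 3.0
    replicates: int = 3
    depth: int | None = 500
    dispersion: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drivers, self.n_candidates, self.n_essential) < 0:
            raise ValueError("gene-set sizes must be >= 0")
        if self.guides_per_gene < 1 or self.n_nt_guides < 1:
            raise ValueError("guide counts must be positive")
        if not 0 < self.targeted_fraction <= 1:
            raise ValueError("targeted_fraction must be in (0, 1]")
        if self.duration <= 0 or self.replicates < 1:
            raise ValueError("duration and replicates must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def gene_names(self) -> pd.DataFrame:
        rows = (
            [(f"DRV{i + 1:02d}", "driver") for i in range(self.n_drivers)]
            + [(f"EC{i + 1:02d}", "cancer_candidate") for i in range(self.n_candidates)]
            + [(f"ESS{i + 1:02d}", "essential") for i in range(self.n_essential)]
        )
        return pd.DataFrame(rows, columns=["gene", "category"])


def _screen_weights(config: ScreenConfig, rng: np.random.Generator):
    genes = config.gene_names()
    guide_rows = []
    for gene, cat in genes.itertuples(index=False):
        for g in range(config.guides_per_gene):
            guide_rows.append((f"{gene}_g{g + 1}", gene, cat))
    for i in range(config.n_nt_guides):
        guide_rows.append((f"NT{i + 1:04d}", None, "NT"))
    guides = pd.DataFrame(guide_rows, columns=["guide_id", "gene", "category"]).set_index(
        "guide_id"
    )
    n_guides = len(guides)
    w0 = rng.dirichlet(np.ones(n_guides))
    s = guides["gene"].map(lambda g: config.fitness.get(g, 0.0)).fillna(0.0).to_numpy()
    growth = np.exp(config.duration * s * (1.0 - config.targeted_fraction))
    w3 = w0 * growth
    w3 = w3 / w3.sum()
    return guides, w0, w3


def gen_screen_counts(config: ScreenConfig) -> GuideTable:
    """Generate a seeded guide count table for the pooled fitness screen."""
    rng = np.random.default_rng(config.seed)
    guides, w0, w3 = _screen_weights(config, rng)
    n_guides = len(guides)
    cols = {}
    for rep in range(1, config.replicates + 1):
        for tp, w in (("week0", w0), ("week3", w3)):
            if config.depth is None:
                cols[(f"rep{rep}", tp)] = w * n_guides * 500.0
                continue
            mu = w * n_guides * config.depth
            if config.dispersion == 0:
                counts = rng.poisson(mu)
            else:
                r = 1.0 / config.dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            cols[(f"rep{rep}", tp)] = counts
    counts = pd.DataFrame(cols, index=guides.index)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["replicate", "timepoint"])
    return GuideTable(guides=guides, counts=counts)


def expected_screen_log2fc(config: ScreenConfig, gene: str | None) -> float:
    """Closed-form expected log2FC of a guide under the generator model.

    ``log2FC = [duration * s_g * (1 - f)] / ln 2 - log2 Z`` where ``Z`` is
    the total library growth factor (the renormalization every guide shares).
    The sampled-count estimate converges to this as depth grows.
    """
    rng = np.random.default_rng(config.seed)
    guides, w0, w3 = _screen_weights(config, rng)
    s = config.fitness.get(gene, 0.0) if gene is not None else 0.0
    growth = np.exp(config.duration * s * (1.0 - config.targeted_fraction))
    z = float(
        np.sum(
            w0
            * np.exp(
                config.duration
                * guides["gene"].map(lambda g: config.fitness.get(g, 0.0)).fillna(0.0).to_numpy()
                * (1.0 - config.targeted_fraction)
            )
        )
    )
    return float(np.log2(growth / z))
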