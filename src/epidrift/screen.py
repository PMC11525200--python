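"""Pooled CRISPR-Cas9 fitness-screen statistics.

A targeted guide library (clonal-expansion drivers, candidate cancer
drivers, essential genes, nontargeting controls) is sequenced at the start
(week 0) and end (week 3) of a competition experiment.  The pipeline:

1. counts-per-million normalization with a pseudocount;
2. per-guide log2 fold change (week 3 vs week 0), averaged over replicates;
3. robust z-scores of guide log2FC against the nontargeting (NT) null
   (median/MAD with the 1.4826 normal-consistency factor);
4. depletion AUC: guides ranked by log2FC ascending (most depleted first),
   AUC of the cumulative fraction of a gene set found versus the fraction of
   the ranked list traversed (trapezoid rule; ~1 = strong depletion, ~0.5 =
   no selection);
5. gene calls by a seeded permutation test on the mean guide log2FC against
   size-matched random draws from the full guide pool, Benjamini-Hochberg
   FDR across genes, and the direction rule: a gene is enriched/depleted
   only if FDR < 0.1 and its median fold change differs from 1 by more than
   10%, else unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GuideTable",
    "GuideStats",
    "AUCResult",
    "CATEGORIES",
    "TIMEPOINTS",
    "normalize_counts",
    "guide_log2fc",
    "guide_zscore",
    "depletion_auc",
    "call_genes",
    "summarize_calls",
    "reference_screen_calls",
]

CATEGORIES = ("driver", "cancer_candidate", "essential", "NT")
TIMEPOINTS = ("week0", "week3")


@dataclass
class GuideTable:
    """gRNA count matrix with gene and category annotation.

    ``guides``: DataFrame indexed by guide_id with columns ``gene`` (None for
    NT controls) and ``category``.  ``counts``: DataFrame indexed by
    guide_id with MultiIndex columns (replicate, timepoint).  Counts are
    nonnegative; fractional counts are permitted only for noiseless expected
    tables produced by the synthetic generator in validation mode.
    """

    guides: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.guides.index.equals(self.counts.index):
            raise ValueError("guides and counts must share the same guide index")
        bad = set(self.guides["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        tps = {tp for _r, tp in self.counts.columns}
        missing = set(TIMEPOINTS) - tps
        if missing:
            raise ValueError(f"missing timepoints: {sorted(missing)}")
        nt = self.guides["category"] == "NT"
        if self.guides.loc[nt, "gene"].notna().any():
            raise ValueError("NT guides must have no gene annotation")

    @property
    def replicates(self) -> list:
        return sorted({r for r, _tp in self.counts.columns})

    def nt_guides(self) -> pd.Index:
        return self.guides.index[self.guides["category"] == "NT"]

    def to_long_frame(self) -> pd.DataFrame:
        long = (
            self.counts.stack(level=[0, 1], future_stack=True)
            .rename("count")
            .reset_index()
        )
        long.columns = ["guide_id", "replicate", "timepoint", "count"]
        ann = self.guides.reset_index().rename(columns={"index": "guide_id"})
        out = long.merge(ann, on="guide_id")
        out["gene"] = out["gene"].fillna("NA")
        return out[["guide_id", "gene", "category", "replicate", "timepoint", "count"]]

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "GuideTable":
        ann = (
            frame[["guide_id", "gene", "category"]]
            .drop_duplicates()
            .set_index("guide_id")
        )
        ann.loc[ann["category"] == "NT", "gene"] = None
        ann["gene"] = ann["gene"].replace({"NA": None})
        counts = frame.pivot_table(
            index="guide_id",
            columns=["replicate", "timepoint"],
            values="count",
            aggfunc="first",
        )
        counts = counts.loc[ann.index]
        return cls(guides=ann, counts=counts)


@dataclass
class GuideStats:
    """Per-guide statistics: normalized abundances, log2FC and z-scores."""

    frame: pd.DataFrame  # index guide_id; columns gene, category, log2fc [, z]
    per_replicate: pd.DataFrame
    nt_median: float | None = None
    nt_mad: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def log2fc(self) -> pd.Series:
        return self.frame["log2fc"]


@dataclass(frozen=True)
class AUCResult:
    """Cumulative-fraction AUC of a gene set over the depletion ranking."""

    gene_set: str
    auc: float
    n_set: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must be in [0, 1]")


def normalize_counts(table: GuideTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts-per-million per sample after adding a pseudocount to every guide."""
    counts = table.counts.astype(float) + pseudocount
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total count")
    return counts / totals * 1e6


def guide_log2fc(table: GuideTable, pseudocount: float = 0.5) -> GuideStats:
    """Per-guide log2 fold change of normalized abundance, week 3 vs week 0.

    Computed per replicate and averaged across replicates.  Guides lacking
    either timepoint in a replicate are excluded from that replicate's
    average (and flagged if no replicate is usable).
    """
    norm = normalize_counts(table, pseudocount)
    per_rep = {}
    for rep in table.replicates:
        cols = {tp for r, tp in norm.columns if r == rep}
        if not set(TIMEPOINTS) <= cols:
            continue
        per_rep[rep] = np.log2(norm[(rep, "week3")] / norm[(rep, "week0")])
    if not per_rep:
        raise ValueError("no replicate has both timepoints")
    per_rep = pd.DataFrame(per_rep)
    frame = table.guides.copy()
    frame["log2fc"] = per_rep.mean(axis=1)
    excluded = frame.index[frame["log2fc"].isna()]
    frame = frame.drop(excluded)
    per_rep = per_rep.drop(excluded)
    return GuideStats(
        frame=frame,
        per_replicate=per_rep,
        meta={"pseudocount": pseudocount, "excluded_guides": list(excluded)},
    )


def guide_zscore(stats: GuideStats, nt_guides=None) -> GuideStats:
    """Robust z-score of guide log2FC against the NT control distribution.

    ``z = (log2FC - median_NT) / (1.4826 * MAD_NT)``; the NT median guide has
    z = 0 by construction.  Requires >= 10 NT guides.
    """
    if nt_guides is None:
        nt_guides = stats.frame.index[stats.frame["category"] == "NT"]
    nt_guides = pd.Index(nt_guides).intersection(stats.frame.index)
    if len(nt_guides) < 10:
        raise ValueError("need >= 10 NT guides for the z-score null")
    nt_lfc = stats.frame.loc[nt_guides, "log2fc"].to_numpy()
    med = float(np.median(nt_lfc))
    mad = float(np.median(np.abs(nt_lfc - med)))
    if mad == 0:
        raise ValueError("NT MAD is zero; z-scores undefined")
    scale = 1.4826 * mad
    stats.frame["z"] = (stats.frame["log2fc"] - med) / scale
    stats.nt_median = med
    stats.nt_mad = mad
    return stats


def _ranked_guides(stats: GuideStats) -> pd.Index:
    # ascending log2FC = most depleted first; ties broken by guide id
    order = stats.frame.assign(_gid=stats.frame.index.astype(str)).sort_values(
        ["log2fc", "_gid"], kind="mergesort"
    )
    return order.index


def depletion_auc(stats: GuideStats, set_guides, gene_set: str = "set") -> AUCResult:
    """AUC of the cumulative fraction of ``set_guides`` over the depletion rank.

    Guides are ranked by log2FC ascending (ties broken lexically by guide
    id).  The curve is the cumulative fraction of set members found against
    the fraction of the ranked list traversed; AUC is by the trapezoid rule.
    A set ranked entirely first attains the maximum ``1 - |S|/(2N)``; a
    uniformly interleaved set gives ~0.5.
    """
    ranked = _ranked_guides(stats)
    set_idx = pd.Index(set_guides)
    missing = set_idx.difference(stats.frame.index)
    if len(missing):
        raise ValueError(f"set guides absent from stats: {list(missing)[:5]}")
    n_total = len(ranked)
    n_set = len(set_idx)
    if n_set == 0 or n_set >= n_total:
        raise ValueError("gene set must be a nonempty strict subset of ranked guides")
    member = np.asarray(ranked.isin(set_idx), dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(member) / n_set])
    x = np.arange(n_total + 1) / n_total
    auc = float(np.trapezoid(cum, x))
    return AUCResult(gene_set=gene_set, auc=auc, n_set=n_set, n_total=n_total)


def call_genes(
    stats: GuideStats,
    fdr_threshold: float = 0.1,
    fc_threshold: float = 0.10,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-gene enriched/depleted/unchanged calls with permutation FDR.

    For each gene the statistic is the mean log2FC of its guides; the null
    is the distribution of means of size-matched random draws from the full
    guide pool (NT and targeted, seeded).  Two-sided p-values are centered
    on the null mean, then BH-adjusted across genes.  A gene is called
    enriched or depleted only if ``fdr < fdr_threshold`` and its median
    guide fold change differs from 1 by more than ``fc_threshold``
    (``|2**median_log2fc - 1| > fc_threshold``); genes with fewer than two
    guides are reported unchanged with a warning flag.
    """
    rng = np.random.default_rng(seed)
    pool = stats.frame["log2fc"].to_numpy()
    targeted = stats.frame[stats.frame["gene"].notna()]
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for gene, grp in targeted.groupby("gene", sort=True):
        lfc = grp["log2fc"].to_numpy()
        n_g = lfc.size
        median_lfc = float(np.median(lfc))
        if n_g < 2:
            rows.append((gene, "unchanged", np.nan, np.nan, median_lfc, n_g, "lt2guides"))
            continue
        if n_g not in null_cache:
            draws = rng.integers(0, pool.size, size=(n_permutations, n_g))
            null_cache[n_g] = pool[draws].mean(axis=1)
        null = null_cache[n_g]
        center = float(null.mean())
        obs = float(lfc.mean())
        p = (1.0 + np.count_nonzero(np.abs(null - center) >= abs(obs - center))) / (
            n_permutations + 1.0
        )
        rows.append((gene, None, min(p, 1.0), np.nan, median_lfc, n_g, ""))
    calls = pd.DataFrame(
        rows,
        columns=["gene", "direction", "p_value", "fdr", "median_log2fc", "n_guides", "warnings"],
    )
    tested = calls["p_value"].notna()
    if tested.any():
        calls.loc[tested, "fdr"] = multipletests(
            calls.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    significant = tested & (calls["fdr"] < fdr_threshold) & (
        np.abs(2.0 ** calls["median_log2fc"] - 1.0) > fc_threshold
    )
    calls.loc[~significant & calls["direction"].isna(), "direction"] = "unchanged"
    calls.loc[significant & (calls["median_log2fc"] > 0), "direction"] = "enriched"
    calls.loc[significant & (calls["median_log2fc"] < 0), "direction"] = "depleted"
    calls.loc[calls["direction"].isna(), "direction"] = "unchanged"
    return calls


def summarize_calls(calls: pd.DataFrame, categories: dict[str, str]) -> pd.DataFrame:
    """Per-category counts of enriched/depleted/unchanged genes.

    ``percent_altered`` is ``100 * (enriched + depleted) / total`` rounded to
    the nearest integer.  Categories present in ``categories`` but without
    any called gene are reported with zeros and an ``empty`` flag.
    """
    unknown = set(calls["gene"]) - set(categories)
    if unknown:
        raise ValueError(f"genes without category: {sorted(unknown)[:5]}")
    rows = []
    for cat in dict.fromkeys(categories.values()):
        genes = calls[calls["gene"].map(categories) == cat]
        n_e = int((genes["direction"] == "enriched").sum())
        n_d = int((genes["direction"] == "depleted").sum())
        n_u = int((genes["direction"] == "unchanged").sum())
        total = n_e + n_d + n_u
        pct = int(round(100.0 * (n_e + n_d) / total)) if total else 0
        rows.append((cat, n_e, n_d, n_u, total, pct, total == 0))
    return pd.DataFrame(
        rows,
        columns=[
            "category",
            "n_enriched",
            "n_depleted",
            "n_unchanged",
            "n_total",
            "percent_altered",
            "empty",
        ],
    )


def reference_screen_calls() -> pd.DataFrame:
    """Reference gene-level outcomes of the esophageal epithelioid fitness screen.

    Direction calls for the 23 clonal-expansion driver genes (9 enriched,
    9 depleted, 5 unchanged) and the 62 candidate esophageal-cancer genes
    (5 enriched, 44 depleted, 13 unchanged).  Only the enriched candidates
    are individually named in the published text; the remaining candidate
    entries carry synthetic placeholder identifiers (EC06..EC62) so that
    category-level summaries -- which depend on counts only -- are exact.
    """
    drivers_enriched = [
        "Trp53", "Ripk4", "Fat1", "Adam10", "Irf6", "Notch1", "Chek2", "Ajuba", "Smad4",
    ]
    drivers_depleted = [
        "Tp63", "Ppm1d", "Cul3", "Pik3ca", "Ccnd1", "Zfp36l2", "Arid2", "Kmt2d", "Nfe2l2",
    ]
    drivers_unchanged = ["Notch3", "Pax9", "Kdm6a", "Arid1a", "Notch2"]
    cand_enriched = ["Chuk", "Plxnb2", "Crebbp", "Bap1", "Zfp750"]
    cand_depleted = [f"EC{i:02d}" for i in range(6, 50)]  # 44 synthetic ids
    cand_unchanged = [f"EC{i:02d}" for i in range(50, 63)]  # 13 synthetic ids
    rows = (
        [(g, "driver", "enriched") for g in drivers_enriched]
        + [(g, "driver", "depleted") for g in drivers_depleted]
        + [(g, "driver", "unchanged") for g in drivers_unchanged]
        + [(g, "cancer_candidate", "enriched") for g in cand_enriched]
        + [(g, "cancer_candidate", "depleted") for g in cand_depleted]
        + [(g, "cancer_candidate", "unchanged") for g in cand_unchanged]
    )
    return pd.DataFrame(rows, columns=["gene", "category", "direction"])
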