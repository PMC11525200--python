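"""Schema-validated TSV readers/writers and the end-to-end pipeline.

Tables are UTF-8 TSV with a mandatory header, '.' decimal separator and no
thousands separators, so round trips are bit-exact.  Each named schema
fixes the column set and dtypes; readers fail with the missing/extra column
names, and malformed numeric cells are reported with their row number.

``run_pipeline`` wires the stages together (synthetic cohort -> trajectory
classification + drift fit; synthetic screen -> guide stats, AUC and gene
calls; competition series -> relative fitness) and writes a JSON manifest
with seeds, versions and output checksums so every artifact is reproducible
from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .culture import relative_fitness
from .sca import classify_cohort, cohort_summary, trajectories_to_frame
from .screen import call_genes, depletion_auc, guide_log2fc, guide_zscore
from .sp_model import fit_drift_kappa
from .synthetic import (
    CompetitionConfig,
    ConfettiCohortConfig,
    ScreenConfig,
    gen_competition_series,
    gen_confetti_trajectories,
    gen_screen_counts,
)

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table", "PipelineConfig", "run_pipeline"]

SCHEMAS: dict[str, dict[str, str]] = {
    "drift_curve": {
        "time_weeks": "float",
        "mean_area_mm2": "float",
        "sca_count": "float",
        "total_area_mm2": "float",
    },
    "trajectories": {
        "sca_id": "str",
        "culture_id": "str",
        "week": "int",
        "area_mm2": "float",
    },
    "sim_trace": {
        "time_weeks": "float",
        "color": "int",
        "component_id": "int",
        "area_mm2": "float",
    },
    "competition": {
        "time_weeks": "float",
        "proportion_focal": "float",
        "n_cells": "float",
    },
    "guide_counts": {
        "guide_id": "str",
        "gene": "str",
        "category": "str",
        "replicate": "str",
        "timepoint": "str",
        "count": "float",
    },
    "gene_calls": {
        "gene": "str",
        "direction": "str",
        "p_value": "float",
        "fdr": "float",
        "median_log2fc": "float",
        "n_guides": "int",
    },
}

_DTYPES = {"float": float, "int": int, "str": str}


class SchemaError(ValueError):
    """Table does not match its declared schema."""


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a TSV against a named schema."""
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in frame.columns]
    extra = [c for c in frame.columns if c not in schema]
    if missing or extra:
        raise SchemaError(
            f"{path.name}: schema '{schema_name}' mismatch"
            + (f"; missing columns {missing}" if missing else "")
            + (f"; unexpected columns {extra}" if extra else "")
        )
    out = {}
    for col, kind in schema.items():
        if kind == "str":
            out[col] = frame[col]
            continue
        blank = frame[col].replace("", np.nan)
        probe = pd.to_numeric(blank, errors="coerce")
        bad = probe.isna() & (frame[col] != "") & (frame[col].str.lower() != "nan")
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise SchemaError(
                f"{path.name}: malformed numeric value {frame[col][bad].iloc[0]!r} "
                f"in column '{col}' at line {row}"
            )
        # astype(float) uses correctly-rounded parsing, keeping round trips
        # bit-exact (pd.to_numeric can lose the last ulp)
        converted = blank.astype(float)
        out[col] = converted if kind == "float" else converted.astype("Int64")
    return pd.DataFrame(out)[list(schema)]


def write_table(frame: pd.DataFrame, path, schema_name: str) -> None:
    """Write a TSV, validating the column set against the schema first."""
    schema = SCHEMAS[schema_name]
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"cannot write '{schema_name}': missing columns {missing}")
    frame[list(schema)].to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineConfig:
    """Configuration of the demo end-to-end pipeline."""

    out_dir: str
    seed: int = 0
    confetti: dict = dc_field(default_factory=dict)
    competition: dict = dc_field(default_factory=dict)
    screen: dict = dc_field(default_factory=dict)
    fit_t0: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "out_dir" not in raw:
            raise SchemaError("pipeline config requires 'out_dir'")
        if not isinstance(raw.get("seed", 0), int):
            raise SchemaError("seed must be an integer")
        return cls(**raw)

    def substream(self, k: int) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        return int(np.random.SeedSequence([self.seed, k]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run synth -> classify/fit -> screen stages and write a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    results: dict[str, object] = {}

    stage = "confetti"
    try:
        cohort_cfg = ConfettiCohortConfig(seed=config.substream(1), **config.confetti)
        trajs = gen_confetti_trajectories(cohort_cfg)
        write_table(trajectories_to_frame(trajs), out / "trajectories.tsv", "trajectories")
        artifacts["trajectories.tsv"] = _sha256(out / "trajectories.tsv")
        classes = classify_cohort(trajs)
        results["class_proportions"] = {
            cls.value: p for cls, p in classes.class_proportions.items()
        }
        summary = cohort_summary(trajs)
        write_table(summary.curve.to_frame(), out / "cohort_summary.tsv", "drift_curve")
        artifacts["cohort_summary.tsv"] = _sha256(out / "cohort_summary.tsv")
        fit = fit_drift_kappa(summary.curve, t0=config.fit_t0, seed=config.substream(2))
        (out / "drift_fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
        artifacts["drift_fit.json"] = _sha256(out / "drift_fit.json")
        results["kappa_hat"] = fit.kappa_hat

        stage = "competition"
        comp_cfg = CompetitionConfig(seed=config.substream(3), **config.competition)
        series = gen_competition_series(comp_cfg)
        frame = pd.DataFrame(
            {
                "time_weeks": series.times,
                "proportion_focal": series.proportion,
                "n_cells": series.n_cells_sampled
                if series.n_cells_sampled is not None
                else np.nan,
            }
        )
        write_table(frame, out / "competition.tsv", "competition")
        artifacts["competition.tsv"] = _sha256(out / "competition.tsv")
        results["relative_fitness_final"] = relative_fitness(series, series.times[-1])

        stage = "screen"
        screen_cfg = ScreenConfig(seed=config.substream(4), **config.screen)
        table = gen_screen_counts(screen_cfg)
        write_table(table.to_long_frame(), out / "guide_counts.tsv", "guide_counts")
        artifacts["guide_counts.tsv"] = _sha256(out / "guide_counts.tsv")
        stats = guide_zscore(guide_log2fc(table))
        ess = stats.frame.index[stats.frame["category"] == "essential"]
        results["essential_auc"] = depletion_auc(stats, ess, "essential").auc
        calls = call_genes(stats, seed=config.substream(5))
        write_table(calls, out / "gene_calls.tsv", "gene_calls")
        artifacts["gene_calls.tsv"] = _sha256(out / "gene_calls.tsv")
        results["n_called"] = int((calls["direction"] != "unchanged").sum())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_params": {
            "confetti": config.confetti,
            "competition": config.competition,
            "screen": config.screen,
            "fit_t0": config.fit_t0,
        },
        "artifacts": artifacts,
        "results": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
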