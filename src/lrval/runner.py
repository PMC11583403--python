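"""Experiment orchestration: scenario sweep, replicate loop, summary tables.

All randomness flows from the master seed through per-(scenario, replicate)
``numpy.random.SeedSequence`` substreams, so a given master seed yields
bit-identical tables. A failing replicate is logged and skipped; the other
replicates continue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectedness as conn
from .breeding import (SCENARIOS, ScenarioResult, run_scenario,
                       scenario_config)
from .blup import herd_blues
from .founders import TraitArchitecture
from .lrstats import aggregate_replicates, scenario_lr_table

logger = logging.getLogger("lrval")


@dataclass
class ExperimentSpec:
    """Full experiment: which scenarios, how many replicates, at what scale."""

    scenarios: tuple[str, ...] = SCENARIOS
    replicates: int = 20
    master_seed: int = 0
    scale: float = 1.0
    arch: TraitArchitecture = field(default_factory=TraitArchitecture)
    connectedness: bool = False  # PEVD / common-sire matrices for WCO & SCO
    outputs: Path | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must be in (0, 1]")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")


def replicate_rng(master_seed: int, scenario: str, replicate: int) -> np.random.Generator:
    """Deterministic substream for one (scenario, replicate) cell."""
    idx = SCENARIOS.index(scenario)
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, idx, replicate])
    )


def genetic_trend(result: ScenarioResult) -> pd.DataFrame:
    """Cohort means of TBV and EBV from the final evaluation, in sigma_g.

    EBVs are the raw animal-effect solutions, the trend a breeding program
    would read off its evaluation output; TBVs are expressed relative to
    the base mean. For an unbiased evaluation the two references coincide
    (the founder-mean EBV is zero).
    """
    state = result.state
    final = result.evaluations[result.cfg.n_years]
    ebv = final.ebv
    rows = []
    for t in range(result.cfg.n_years + 1):
        ids = state.ids_born(t)
        rows.append({
            "scenario": result.cfg.name,
            "year": t,
            "mean_tbv_sg": float(
                (state.tbv[ids - 1].mean() - state.base_tbv_mean) / result.sigma_g
            ),
            "mean_ebv_sg": float(ebv[ids - 1].mean() / result.sigma_g),
        })
    return pd.DataFrame(rows)


def run_replicate(
    scenario: str,
    spec: ExperimentSpec,
    replicate: int,
) -> dict:
    """One (scenario, replicate) cell: simulate, evaluate, summarise."""
    cfg = scenario_config(scenario, spec.scale)
    rng = replicate_rng(spec.master_seed, scenario, replicate)
    keep = spec.connectedness and cfg.fixed_effects == "mean_and_herd_year"
    result = run_scenario(cfg, spec.arch, rng, keep_final_system=keep)
    out = {
        "lr": scenario_lr_table(result),
        "trend": genetic_trend(result),
        "counts": result.structural_counts(),
    }
    if cfg.fixed_effects == "mean_and_herd_year":
        out["herd_blues"] = herd_blues(
            result.evaluations[cfg.n_years], cfg.n_herds
        )
    if keep:
        final = result.evaluations[cfg.n_years]
        groups = conn.contemporary_groups(result.state, cfg.n_years)
        out["pevd"] = conn.pevd_matrix(final, groups)
        out["common_sires"] = conn.common_sires(result.state.sire_eval, groups)
        final.drop_system()
    return out


def run_experiment(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    """Scenario x replicate sweep; returns the summary tables.

    Tables: ``lr_summary`` (Tables 1-4 layout), ``trend`` (genetic-gain
    trajectories), ``herd_blues`` (re-based herd BLUE means with 95% CI),
    ``counts`` (pedigree census per replicate) and, when requested,
    ``connectedness`` (mean cross-herd scaled PEVD and common sires).
    """
    lr_tables: dict[str, list[pd.DataFrame]] = {}
    trends, counts, blues, conn_rows = [], [], [], []
    for scenario in spec.scenarios:
        for r in range(spec.replicates):
            try:
                rep = run_replicate(scenario, spec, r)
            except Exception:
                logger.exception("replicate %d of %s failed; continuing",
                                 r, scenario)
                continue
            lr_tables.setdefault(scenario, []).append(rep["lr"])
            t = rep["trend"].copy()
            t["replicate"] = r
            trends.append(t)
            counts.append({"scenario": scenario, "replicate": r, **rep["counts"]})
            if "herd_blues" in rep:
                for h, v in enumerate(rep["herd_blues"], start=1):
                    blues.append({"scenario": scenario, "replicate": r,
                                  "herd": h, "blue": float(v)})
            if "pevd" in rep:
                conn_rows.append({
                    "scenario": scenario, "replicate": r,
                    "cross_herd_pevd": conn.cross_herd_summary(rep["pevd"]),
                    "cross_herd_common_sires":
                        conn.cross_herd_summary(rep["common_sires"]),
                })

    tables: dict[str, pd.DataFrame] = {}
    tables["lr_summary"] = pd.concat(
        [aggregate_replicates(ts) for ts in lr_tables.values()],
        ignore_index=True,
    )
    trend = pd.concat(trends, ignore_index=True)
    tables["trend"] = (
        trend.groupby(["scenario", "year"], sort=False)
        .agg(mean_tbv_sg=("mean_tbv_sg", "mean"),
             mean_ebv_sg=("mean_ebv_sg", "mean"),
             sd_tbv_sg=("mean_tbv_sg", "std"),
             sd_ebv_sg=("mean_ebv_sg", "std"))
        .reset_index()
    )
    tables["counts"] = pd.DataFrame(counts)
    if blues:
        bdf = pd.DataFrame(blues)
        g = bdf.groupby(["scenario", "herd"], sort=False)["blue"]
        summary = g.agg(["mean", "std", "count"]).reset_index()
        sem = summary["std"] / np.sqrt(summary["count"])
        summary["ci_low"] = summary["mean"] - 1.96 * sem
        summary["ci_high"] = summary["mean"] + 1.96 * sem
        tables["herd_blues"] = summary
    if conn_rows:
        cdf = pd.DataFrame(conn_rows)
        tables["connectedness"] = (
            cdf.groupby("scenario", sort=False)
            .agg(cross_herd_pevd=("cross_herd_pevd", "mean"),
                 cross_herd_common_sires=("cross_herd_common_sires", "mean"))
            .reset_index()
        )

    if spec.outputs is not None:
        outdir = Path(spec.outputs)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
    return tables
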