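"""End-to-end orchestration: one config, three analyses, uniform reports.

A :class:`RunConfig` points at the input files and carries the analysis
parameters (all defaults are the standard ones: minimum 5 occurrences per
species, 10° background buffer, R = 100 occupancy grids, 100 permutation
replicates, 1,000 Brownian simulations, median summaries, Euclidean
disparity).  Each stage logs counts in/out and returns JSON-serializable
reports that embed the resolved config for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate, core_io, disparity, overlap, signal

logger = logging.getLogger("phyloniche")


@dataclass
class RunConfig:
    """Paths and parameters of a full run."""

    tree: str = ""
    occurrences: str = ""
    host_occurrences: str = ""
    rasters: dict[str, str] = field(default_factory=dict)
    association: str = ""
    groups: str = ""
    out_dir: str = "results"

    min_n: int = 5
    buffer: float = 10.0
    R: int = 100
    reps: int = 100
    n_sim: int = 1000
    summary: str = "median"
    metric: str = "euclidean"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _load_filtered(cfg: RunConfig):
    """Shared front half: tree + occurrences + grouping + min-n filter."""
    if not cfg.tree or not Path(cfg.tree).exists():
        raise FileNotFoundError(f"tree file not found: {cfg.tree!r}")
    tree = core_io.read_tree(cfg.tree)
    occ = core_io.read_occurrences(cfg.occurrences)
    if cfg.groups:
        mapping, drop = core_io.read_species_groups(cfg.groups)
        occ = core_io.apply_species_groups(occ, mapping, drop)
    occ, tree = core_io.filter_min_occurrences(occ, tree, min_n=cfg.min_n)
    return tree, occ


def _extract_traits(cfg: RunConfig, tree, occ):
    rasters = core_io.read_raster_stack(cfg.rasters)
    values = climate.extract_at_points(rasters, occ)
    summaries = climate.summarize_species(values)
    # re-filter in case nodata dropped a species below the threshold
    enough = summaries[("n_used", "")] >= cfg.min_n
    keep = sorted(set(summaries.index[enough]) & set(tree.tip_names))
    if len(keep) < len(tree.tip_names):
        tree = tree.prune_to(keep)
        summaries = summaries.loc[keep]
    return rasters, values, summaries, tree


def run_extract(cfg: RunConfig) -> dict:
    """Extraction stage: per-record climate values and the trait matrix."""
    tree, occ = _load_filtered(cfg)
    _, values, summaries, tree = _extract_traits(cfg, tree, occ)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    values.to_csv(out / "extraction.csv", index=False)
    tm = climate.trait_matrix(summaries, stat=cfg.summary)
    tm.data.to_csv(out / "traits.csv")
    return {"config": cfg.resolved(), "n_records": len(values),
            "n_species": len(tm.species), "traits": str(out / "traits.csv")}


def run_signal(cfg: RunConfig) -> dict:
    """Pagel's λ per variable for median, min and max summaries."""
    tree, occ = _load_filtered(cfg)
    _, _, summaries, tree = _extract_traits(cfg, tree, occ)
    rows = []
    for stat in climate.SUMMARY_STATS:
        tm = climate.trait_matrix(summaries, stat=stat)
        for res in signal.fit_all(tree, tm, summary_used=stat):
            rows.append(res.to_dict())
    report = {"config": cfg.resolved(), "results": rows}
    _write_report(cfg, "signal", report)
    pd.DataFrame(rows).to_csv(Path(cfg.out_dir) / "signal.csv", index=False)
    return report


def run_dtt(cfg: RunConfig) -> dict:
    """Disparity-through-time with a Brownian envelope."""
    tree, occ = _load_filtered(cfg)
    _, _, summaries, tree = _extract_traits(cfg, tree, occ)
    tm = climate.standardize(climate.trait_matrix(summaries,
                                                  stat=cfg.summary))
    observed, env = disparity.dtt_envelope(tree, tm, n_sim=cfg.n_sim,
                                           seed=cfg.seed, metric=cfg.metric)
    report = {"config": cfg.resolved(), "observed": observed.to_dict(),
              "envelope": env.to_dict()}
    _write_report(cfg, "dtt", report)
    return report


def run_equivalency_batch(cfg: RunConfig) -> pd.DataFrame:
    """Niche-equivalency tests for every insect entity in the association.

    One row per entity: observed D, p-value, occurrence count, host
    count.  Entities with fewer than ``min_n`` usable occurrences get NA
    rows; any entity-level failure is recorded as NA with its reason and
    the batch continues.
    """
    assoc = core_io.read_host_association(cfg.association)
    if not assoc:
        raise ValueError("empty association mapping")
    insect_occ = core_io.read_occurrences(cfg.occurrences)
    host_occ = core_io.read_occurrences(cfg.host_occurrences)
    if cfg.groups:
        mapping, drop = core_io.read_species_groups(cfg.groups)
        insect_occ = core_io.apply_species_groups(insect_occ, mapping, drop)
    rasters = core_io.read_raster_stack(cfg.rasters)
    rows = []
    for i, insect in enumerate(sorted(assoc)):
        occ_i = insect_occ[insect_occ["species"] == insect]
        n_hosts = len(assoc[insect])
        row = {"entity": insect, "D_obs": np.nan, "p_value": np.nan,
               "n_occurrences": len(occ_i), "n_hosts": n_hosts,
               "note": ""}
        if len(occ_i) < cfg.min_n:
            row["note"] = f"fewer than {cfg.min_n} occurrences"
            rows.append(row)
            continue
        try:
            hosts = overlap.host_union(insect, assoc, host_occ)
            res = overlap.equivalency_test(
                occ_i, hosts, rasters, reps=cfg.reps,
                seed=int((cfg.seed * 1000003 + i) % (2 ** 31)),
                R=cfg.R, buffer=cfg.buffer)
        except (ValueError, KeyError) as exc:
            row["note"] = str(exc)
            rows.append(row)
            continue
        row.update({"D_obs": res.d_obs, "p_value": res.p_value,
                    "n_occurrences": res.n_a})
        rows.append(row)
    table = pd.DataFrame(rows)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "equivalency.csv", index=False)
    return table


def _write_report(cfg: RunConfig, name: str, report: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{name}.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
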