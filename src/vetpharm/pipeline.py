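"""End-to-end orchestration: simulate/load → map → rates → diversity → network → stats.

Produces per-stage CSV outputs plus a deterministic JSON summary; any stage
failure aborts with a stage-named error while preserving the outputs written
so far.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import diversity, network, rates, stats, synthdata, textmap
from .errors import PipelineStageError, UndefinedResultError, ValidationError
from .taxonomy import load_taxonomy

logger = logging.getLogger(__name__)

#: the five families examined for diversity: the infection-treating families
DEFAULT_PD_PFS = (
    "antibiotic",
    "antimycotic",
    "ectoparasiticide",
    "endectocide",
    "endoparasiticide",
)


@dataclass
class PipelineConfig:
    """Pipeline inputs: either a simulation block or paths to input CSVs."""

    out_dir: Union[str, Path] = "vetpharm_out"
    seed: int = 0
    simulate: Optional[dict] = None
    records_csv: Optional[str] = None
    taxonomy_csv: Optional[str] = None
    rules_csv: Optional[str] = None
    n_boot: int = 1000
    pd_pfs: tuple[str, ...] = DEFAULT_PD_PFS
    node_frac: float = 0.005
    lpa_runs: int = 20
    species: tuple[str, ...] = synthdata.SPECIES

    def validate(self) -> None:
        if self.simulate is None and self.records_csv is None:
            raise ValidationError(
                "config must provide either a 'simulate' block or records_csv"
            )
        if self.records_csv is not None and (
            self.taxonomy_csv is None or self.rules_csv is None
        ):
            raise ValidationError(
                "records_csv requires taxonomy_csv and rules_csv"
            )
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.pd_pfs, list):
            cfg.pd_pfs = tuple(cfg.pd_pfs)
        if isinstance(cfg.species, list):
            cfg.species = tuple(cfg.species)
        cfg.validate()
        return cfg


SUMMARY_REQUIRED_KEYS = {
    "dataset": dict,
    "mapping": dict,
    "rates": dict,
    "diversity": dict,
    "network": dict,
    "stats": dict,
}


def validate_summary(summary: dict) -> None:
    """Check the summary bundle against the shipped schema (top-level shape)."""
    for key, typ in SUMMARY_REQUIRED_KEYS.items():
        if key not in summary:
            raise ValidationError(f"summary is missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValidationError(f"summary[{key!r}] must be a {typ.__name__}")
    for sp, block in summary["rates"].items():
        if "prescription_frequency" not in block:
            raise ValidationError(f"rates[{sp!r}] lacks prescription_frequency")


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the JSON-ready summary."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    sim_seed, boot_seed, lpa_seed, _ = seeds
    summary: dict = {}
    t_stage = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t_stage
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t_stage)
        t_stage = time.perf_counter()

    # -- inputs -------------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim_cfg = synthdata.SynthConfig.from_dict(
                {**config.simulate, "seed": config.simulate.get("seed", sim_seed)}
            )
            records, gt = synthdata.generate_dataset(sim_cfg)
            synthdata.write_dataset(records, gt, outdir / "synthetic")
            taxonomy = synthdata.builtin_taxonomy()
            rules = synthdata.builtin_ruleset(taxonomy)
            summary["dataset"] = {
                "source": "simulated",
                **gt.summary_dict(),
            }
            summary["dataset"].pop("p_prescribe_by_practice", None)
        else:
            records = pd.read_csv(config.records_csv, dtype=str,
                                  keep_default_na=False)
            taxonomy = load_taxonomy(config.taxonomy_csv)
            rules = textmap.load_rules(config.rules_csv, taxonomy)
            summary["dataset"] = {
                "source": str(config.records_csv),
                "n_consultations": int(len(records)),
            }
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, str(exc)) from exc
    tick(stage)

    # -- mapping ------------------------------------------------------------
    stage = "map"
    try:
        events, report = textmap.map_consultations(records, rules)
        events.to_csv(outdir / "events.csv", index=False)
        with open(outdir / "map_report.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        summary["mapping"] = report.as_dict()
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    tick(stage)

    # -- rates --------------------------------------------------------------
    stage = "rates"
    try:
        rate_rows = []
        summary["rates"] = {}
        for sp in config.species:
            recs_sp = records[records["species"] == sp]
            if recs_sp.empty:
                continue
            flags = rates.has_event_flag(recs_sp, events[events["species"] == sp])
            recs_sp = recs_sp.assign(_has_rx=flags.to_numpy())
            est = rates.cluster_bootstrap_dual(
                lambda df: df["_has_rx"].mean(), recs_sp,
                n_boot=config.n_boot, seed=boot_seed,
            )
            block = {
                "prescription_frequency": est.statistic,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "cluster_level": est.cluster_level,
                "authorisation": rates.authorisation_breakdown(events, sp)
                if not events[events["species"] == sp].empty
                else {},
                "rate_per_10k": {},
            }
            for pf in sorted(events.loc[events["species"] == sp, "pf"].unique()):
                block["rate_per_10k"][pf] = rates.rate_per_10k(
                    records, events, pf, species=sp
                )
                rate_rows.append(
                    {"species": sp, "pf": pf,
                     "rate_per_10k": block["rate_per_10k"][pf]}
                )
            summary["rates"][sp] = block
        pd.DataFrame(rate_rows).to_csv(outdir / "rates.csv", index=False)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    tick(stage)

    # -- diversity ----------------------------------------------------------
    stage = "diversity"
    try:
        pd_frames = []
        summary["diversity"] = {}
        for pf in config.pd_pfs:
            summary["diversity"][pf] = {}
            for sp in config.species:
                table = diversity.practice_pd_table(events, pf, species=sp)
                if table.empty:
                    continue
                table.insert(1, "species", sp)
                pd_frames.append(table)
                defined = table["pd"].dropna()
                median = defined.median() if len(defined) else float("nan")
                summary["diversity"][pf][sp] = {
                    "median_pd": None if pd.isna(median) else float(median),
                    "n_practices": int(len(table)),
                    "n_defined": int(table["pd"].notna().sum()),
                }
        pd_table = (
            pd.concat(pd_frames, ignore_index=True)
            if pd_frames
            else pd.DataFrame(
                columns=["practice_id", "species", "pf", "pd", "NP",
                         "n_classes_prescribed"]
            )
        )
        pd_table.to_csv(outdir / "pd.csv", index=False)

        # antibiotic benchmarking matrix where enough practices contribute
        summary["diversity"]["benchmark"] = {}
        for sp in config.species:
            ab = pd_table[
                (pd_table["pf"] == "antibiotic") & (pd_table["species"] == sp)
            ].set_index("practice_id")
            recs_sp = records[records["species"] == sp]
            if len(ab) < 5 or recs_sp.empty:
                continue
            flags = rates.has_event_flag(recs_sp, events[
                (events["species"] == sp) & (events["pf"] == "antibiotic")
            ])
            freq = (
                recs_sp.assign(_f=flags.to_numpy())
                .groupby("practice_id")["_f"].mean()
            )
            try:
                matrix = diversity.benchmark_quintile_matrix(freq, ab["pd"])
            except ValidationError:
                continue
            matrix.to_csv(outdir / f"benchmark_antibiotic_{sp}.csv")
            summary["diversity"]["benchmark"][sp] = matrix.to_numpy().tolist()
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    tick(stage)

    # -- network ------------------------------------------------------------
    stage = "network"
    try:
        summary["network"] = {}
        for sp in config.species:
            ev_sp = events[events["species"] == sp]
            if ev_sp.empty:
                continue
            sets = network.consult_pf_sets(ev_sp)
            g = network.build_network(ev_sp)
            sg = network.sparsify(g, node_frac=config.node_frac)
            groups = network.detect_groups(sg, seed=lpa_seed,
                                           n_runs=config.lpa_runs)
            network.write_network(sg, outdir, groups=groups,
                                  prefix=f"network_{sp}")
            pc_g = network.build_pc_network(ev_sp)
            network.write_network(pc_g, outdir, prefix=f"network_pc_{sp}")
            summary["network"][sp] = {
                "coprescription_rate": network.coprescription_rate(sets),
                "n_nodes": sg.number_of_nodes(),
                "n_edges": sg.number_of_edges(),
                "n_groups": len(set(groups.values())),
                "groups": dict(sorted(groups.items())),
            }
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    tick(stage)

    # -- comparative stats --------------------------------------------------
    stage = "stats"
    try:
        summary["stats"] = {"wilcoxon": {}, "kendall": {}}
        pd_csv = pd.read_csv(outdir / "pd.csv") if (outdir / "pd.csv").exists() \
            else pd.DataFrame()
        for pf in config.pd_pfs:
            by_species = {
                sp: grp["pd"].to_numpy()
                for sp, grp in pd_csv[pd_csv["pf"] == pf].groupby("species")
                if grp["pd"].notna().any()
            }
            if len(by_species) >= 2:
                comps = stats.pairwise_wilcoxon(by_species)
                summary["stats"]["wilcoxon"][pf] = [
                    {"pair": [c.group_a, c.group_b], "statistic": c.statistic,
                     "raw_p": c.raw_p, "adj_p": c.adj_p,
                     "significant": c.significant}
                    for c in comps
                ]
            # diversity vs contributed consultations, per species
            summary["stats"]["kendall"][pf] = {}
            for sp, grp in pd_csv[pd_csv["pf"] == pf].groupby("species"):
                counts = (
                    records[records["species"] == sp]
                    .groupby("practice_id")["consultation_id"].count()
                )
                merged = grp.set_index("practice_id").join(
                    counts.rename("n_consults"), how="inner"
                ).dropna(subset=["pd"])
                if len(merged) < 3:
                    continue
                try:
                    corr = stats.kendall_correlation(
                        merged["pd"], merged["n_consults"]
                    )
                except (UndefinedResultError, ValidationError):
                    continue
                summary["stats"]["kendall"][pf][sp] = {
                    "tau": corr.tau, "p": corr.p_value, "n": corr.n,
                }
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    tick(stage)

    summary = _round_floats(summary)
    validate_summary(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
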