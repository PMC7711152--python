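"""Umbrella pipeline: simulate → filter → transform → stats → amendment model.

A single config mapping drives every stage; the resolved config, per-stage
removal ledgers, statistics (with their seeds) and amendment-model
conventions are collected into a run report that suffices to replay the run.
"""

from __future__ import annotations

import copy
from pathlib import Path

from . import __version__
from .amendment import (
    ActivityInputs,
    IncubationSchedule,
    PlaneSourceModel,
    SpongeAmendment,
    areal_source_strength,
    diffused_carbon_report,
    per_cell_rate,
    scenario_duration,
    sponge_budget,
)
from .community import anosim, bray_curtis_matrix
from .diversity import chao1, shannon_index
from .filters import apply_filter_chain, fourth_root_transform
from .io import (
    read_metadata,
    read_otu_table,
    write_distance_matrix,
    write_metadata,
    write_otu_table,
    write_run_report,
)
from .ordination import nmds
from .otu import OtuTable, SampleMetadata, ValidationError, to_relative_abundance
from .synth import SyntheticCommunitySpec, generate_control_samples, generate_otu_table

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "deepamend_out",
    "simulate": {"enabled": False, "n_controls": 3, "spec": {}},
    "input": {"otu_table": None, "metadata": None, "controls": None},
    "filter": {
        "enabled": True,
        "singletons": True,
        "threshold": 1e-4,
        "control_cutoff": 5e-4,
    },
    "stats": {
        "enabled": True,
        "transform": "fourthroot",
        "group_col": "substrate_bin",
        "permutations": 999,
        "nmds_k": 2,
        "nmds_restarts": 20,
    },
    "amendment": {
        "enabled": True,
        "n_sponges": 5,
        "mean_mass": 0.37,
        "carbon_fraction": 0.4744,
        "nitrogen_fraction": 0.1615,
        "well_diameter": 0.086,
        "diffusion_coefficient": 1.06e-9,
        "near_offset": 0.25,
        "far_offset": 2.0,
        "water_volume": 10.6,
        "convention": "paper_volume",
        "cell_density": 4.1e6,
        "scenarios": [
            {"t_days": 37, "duration_scenario": "midpoint3_to_midpoint5"},
            {"t_days": 74, "duration_scenario": "deploy3_to_mid_recovery3_4"},
        ],
    },
}


def resolve_config(config: dict | None) -> dict:
    """Overlay user options on the defaults (shallow per-stage merge)."""
    out = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _simulate(cfg: dict, seed: int):
    spec = SyntheticCommunitySpec(seed=seed, **cfg["simulate"].get("spec", {}))
    table, meta = generate_otu_table(spec)
    controls = None
    if spec.contaminant_otus:
        controls = generate_control_samples(spec, cfg["simulate"]["n_controls"])
    return table, meta, controls


@_stage("load")
def _load(cfg: dict):
    inp = cfg["input"]
    if inp["otu_table"] is None:
        raise ValidationError("no input otu_table and simulate stage disabled")
    table = read_otu_table(inp["otu_table"])
    meta = read_metadata(inp["metadata"]) if inp["metadata"] else None
    controls = read_otu_table(inp["controls"]) if inp["controls"] else None
    return table, meta, controls


@_stage("stats")
def _stats(
    cfg: dict, table: OtuTable, meta: list[SampleMetadata] | None, seed: int
) -> dict:
    scfg = cfg["stats"]
    rel = to_relative_abundance(table)
    if scfg["transform"] == "fourthroot":
        rel = fourth_root_transform(rel)
    elif scfg["transform"] not in ("none", None):
        raise ValidationError(f"unknown transform {scfg['transform']!r}")
    dm = bray_curtis_matrix(rel)
    ord_res = nmds(
        dm, k=scfg["nmds_k"], n_restarts=scfg["nmds_restarts"], seed=seed
    )
    out = {
        "transform": scfg["transform"],
        "nmds_stress": ord_res.stress,
        "nmds_converged": ord_res.converged,
        "nmds_seed": seed,
        "alpha": {
            sid: {
                "shannon": shannon_index(table.counts.loc[sid]),
                "chao1": chao1(table.counts.loc[sid]),
            }
            for sid in table.sample_ids
        },
    }
    if meta is not None:
        by_id = {m.sample_id: m for m in meta}
        groups = [
            getattr(by_id[sid], scfg["group_col"]) for sid in table.sample_ids
        ]
        res = anosim(dm, groups, n_permutations=scfg["permutations"], seed=seed)
        out["anosim"] = {
            "group_col": scfg["group_col"],
            "R": res.R,
            "p": res.p,
            "n_permutations": res.n_permutations,
            "exhaustive": res.exhaustive,
            "seed": seed,
        }
    return out, dm, ord_res


@_stage("amendment")
def _amendment(cfg: dict) -> dict:
    acfg = cfg["amendment"]
    amendment = SpongeAmendment(
        n_sponges=acfg["n_sponges"],
        mean_mass=acfg["mean_mass"],
        carbon_fraction=acfg["carbon_fraction"],
        nitrogen_fraction=acfg["nitrogen_fraction"],
    )
    c_mass, n_mass, c_mol = sponge_budget(amendment)
    n_areal = areal_source_strength(c_mol, acfg["well_diameter"])
    model = PlaneSourceModel(
        N=n_areal,
        D=acfg["diffusion_coefficient"],
        well_diameter=acfg["well_diameter"],
        near_offset=acfg["near_offset"],
        far_offset=acfg["far_offset"],
        water_volume=acfg["water_volume"],
        convention=acfg["convention"],
    )
    schedule = IncubationSchedule()
    out = {
        "carbon_mass_g": c_mass,
        "nitrogen_mass_g": n_mass,
        "carbon_moles": c_mol,
        "areal_source_strength_mol_m2": n_areal,
        "convention": acfg["convention"],
        "scenarios": [],
    }
    for sc in acfg["scenarios"]:
        rep = diffused_carbon_report(model, sc["t_days"])
        duration = scenario_duration(schedule, sc["duration_scenario"])
        rate = per_cell_rate(
            ActivityInputs(
                carbon=rep["closed_form_mol"],
                duration=duration,
                cell_density=acfg["cell_density"],
                water_volume=acfg["water_volume"],
            )
        )
        rep.update(
            {
                "duration_scenario": sc["duration_scenario"],
                "duration_days": duration,
                "per_cell_rate_fmol_day_closed_form": rate,
            }
        )
        out["scenarios"].append(rep)
    return out


def run_pipeline(config: dict | None = None, output_dir=None) -> dict:
    """Execute the configured stages and return (and optionally write) a run report."""
    cfg = resolve_config(config)
    seed = cfg.get("seed")
    if seed is None and (cfg["simulate"]["enabled"] or cfg["stats"]["enabled"]):
        raise ValidationError("a seed is required when stochastic stages are enabled")
    report: dict = {"version": __version__, "config": copy.deepcopy(cfg)}

    if cfg["simulate"]["enabled"]:
        table, meta, controls = _simulate(cfg, seed)
    else:
        table, meta, controls = _load(cfg)

    if cfg["filter"]["enabled"]:
        fcfg = cfg["filter"]
        table, ledger = apply_filter_chain(
            table,
            controls,
            singletons=fcfg["singletons"],
            threshold=fcfg["threshold"],
            control_cutoff=fcfg["control_cutoff"],
        )
        report["filter_ledger"] = {k: list(v) for k, v in ledger.items()}
        report["n_otus_after_filtering"] = table.shape[1]

    dm = ord_res = None
    if cfg["stats"]["enabled"]:
        stats_out, dm, ord_res = _stats(cfg, table, meta, seed)
        report["stats"] = stats_out

    if cfg["amendment"]["enabled"]:
        report["amendment"] = _amendment(cfg)

    out_dir = output_dir or cfg.get("output_dir")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_otu_table(table, out / "filtered_counts.tsv")
        if meta is not None:
            write_metadata(meta, out / "metadata.tsv")
        if dm is not None:
            write_distance_matrix(dm, out / "bray_curtis.tsv")
        if ord_res is not None:
            import pandas as pd

            pd.DataFrame(
                ord_res.coordinates,
                index=ord_res.sample_ids or table.sample_ids,
                columns=[f"NMDS{i + 1}" for i in range(ord_res.coordinates.shape[1])],
            ).to_csv(out / "nmds_coordinates.tsv", sep="\t", index_label="sample_id")
        write_run_report(report, out / "run_report.yaml")
    return report
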