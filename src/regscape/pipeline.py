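"""Condition-comparison orchestration.

Runs the full analysis battery over a set of labelled conditions (one
control plus any number of perturbed conditions, e.g. phosphorylation
states), producing per-condition summary tables (distribution summaries
of end-to-end distance, radius of gyration and total SASA under both
accountings; secondary-structure composition; Ramachandran-region
populations; contact occupancy matrices; tICA landscape with cluster
model selection) and condition-minus-control difference products.

The report bundle is a plain nested dict; ``write_report`` serialises it
to CSV/JSON files plus a manifest recording the config hash and seeds so
a run is exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chem_topology import (
    Topology,
    charged_groups,
    counterion_count,
    formal_net_charge,
    parse_sequence,
)
from .contacts import occupancy_difference, saltbridge_occupancy
from .ensemble_stats import summarize
from .geometry import end_to_end, pair_distance, radius_of_gyration
from .landscape import cluster_scan, featurize, fit_tica, free_energy_surface
from .ramachandran import (
    DEFAULT_REGIONS,
    compute_dihedrals,
    population_difference,
    region_populations,
)
from .sasa import residue_sasa_series, sasa_difference, total_sasa
from .secstruct import assign, composition
from .synthetic import MarkovDihedralModel, dihedral_ensemble
from .trajectory_io import Trajectory, read_ensemble, write_ensemble

__all__ = ["ConditionSpec", "PipelineError", "run_analysis", "write_report",
           "crystal_checks", "DEFAULT_BASIN_MODEL"]

log = logging.getLogger("regscape")


class PipelineError(RuntimeError):
    """Raised when an analysis stage fails; carries the stage name in the
    message and any partial results in ``partial_bundle``."""

    partial_bundle: dict

# Disordered-chain basin model used when a condition asks for a synthetic
# trajectory without specifying its own dynamics: PPII, alpha and beta
# basins with PPII/coil-dominated occupancy, as expected for an IDR.
DEFAULT_BASIN_MODEL = MarkovDihedralModel(
    centers=((-75.0, 145.0), (-63.0, -43.0), (-120.0, 130.0)),
    transition=(
        (0.95, 0.02, 0.03),
        (0.06, 0.90, 0.04),
        (0.05, 0.02, 0.93),
    ),
    jitter_deg=12.0,
)


@dataclass
class ConditionSpec:
    label: str
    topology: Topology
    source: dict
    role: str = "condition"  # "control" | "condition"


def _condition_specs(config: dict) -> list[ConditionSpec]:
    seq = config["sequence"]
    first = int(config.get("first_residue", 1))
    specs = []
    for c in config.get("conditions", []):
        top = parse_sequence(
            seq,
            first,
            c.get("phosphosites", ()),
            phospho_charge=int(config.get("phospho_charge", -1)),
            his_protonation=config.get("his_protonation", "neutral"),
        )
        specs.append(
            ConditionSpec(
                label=c["label"],
                topology=top,
                source=c.get("source", {"synthetic": {}}),
                role=c.get("role", "condition"),
            )
        )
    roles = [s.role for s in specs]
    if specs and roles.count("control") != 1:
        raise ValueError("exactly one condition must have role='control'")
    return specs


def _load_trajectory(spec: ConditionSpec, config: dict) -> Trajectory:
    src = spec.source
    if "pdb" in src:
        return read_ensemble(src["pdb"], spec.topology)
    if "trajectory" in src:
        return read_ensemble(
            src["trajectory"], spec.topology, top_path=src.get("topology_pdb")
        )
    syn = dict(src.get("synthetic", {}))
    seed = int(syn.pop("seed", config.get("seed", 0)))
    n_frames = int(syn.pop("n_frames", 200))
    if "model" in syn:
        m = syn["model"]
        model = MarkovDihedralModel(
            centers=tuple(map(tuple, m["centers"])),
            transition=tuple(map(tuple, m["transition"])),
            jitter_deg=float(m.get("jitter_deg", 12.0)),
        )
    else:
        model = DEFAULT_BASIN_MODEL
    traj, _states = dihedral_ensemble(
        spec.topology, model, n_frames, seed,
        pin_first=bool(syn.pop("pin_first", False)),
    )
    return traj


def _analyze_condition(
    spec: ConditionSpec, traj: Trajectory, analysis: dict
) -> dict:
    t0 = time.time()
    out: dict = {"label": spec.label, "role": spec.role, "n_frames": traj.n_frames}
    top = spec.topology
    sites = set(top.phosphosites)

    out["charges"] = {
        "n_charged_groups": len(charged_groups(top)),
        "group_charge_sum": sum(g.sign for g in charged_groups(top)),
        "formal_net_charge": formal_net_charge(top),
        "counterions": counterion_count(formal_net_charge(top)),
    }

    ee = end_to_end(traj)
    rg = radius_of_gyration(
        traj, mass_weighted=bool(analysis.get("rg_mass_weighted", True))
    )
    sasa = residue_sasa_series(
        traj,
        probe=float(analysis.get("probe", 0.14)),
        n_points=int(analysis.get("sasa_points", 240)),
    )
    sasa_total = total_sasa(sasa)
    sasa_nophos = total_sasa(sasa, exclude_sites=sites)
    out["series"] = {"EE_DIST": ee, "R_G": rg, "SASA": sasa_total,
                     "SASA_excl_sites": sasa_nophos}
    out["sasa_matrix"] = sasa
    out["table1"] = {
        name: summarize(series).as_dict()
        for name, series in out["series"].items()
    }

    ss = assign(traj, phosphosites=sites)
    out["assignment"] = ss
    out["table2"] = composition(ss)

    out["ramachandran"] = region_populations(traj, DEFAULT_REGIONS)

    out["saltbridges"] = saltbridge_occupancy(
        traj, top, cutoff=float(analysis.get("saltbridge_cutoff", 0.35))
    )
    out["hbond_map"] = saltbridge_occupancy(
        traj, top, cutoff=float(analysis.get("hbond_cutoff", 0.30))
    )

    phi, psi = compute_dihedrals(traj)
    feats = featurize(phi, psi)
    lag = int(analysis.get("lag", 5))
    tica = fit_tica(feats, lag=lag,
                    n_components=int(analysis.get("n_components", 2)))
    fes = free_energy_surface(
        tica.projection, grid_size=int(analysis.get("grid_size", 60))
    )
    k_lo, k_hi = analysis.get("k_range", (2, 10))
    models, k_sel = cluster_scan(
        tica.projection,
        k_range=range(int(k_lo), int(k_hi) + 1),
        linkage=analysis.get("linkage", "ward"),
        min_population=int(analysis.get("min_population", 10)),
    )
    out["landscape"] = {
        "tica": tica,
        "surface": fes,
        "models": models,
        "selected_k": k_sel,
        "scan_table": pd.DataFrame(
            {
                "k": list(models),
                "silhouette": [m.silhouette for m in models.values()],
                "davies_bouldin": [m.davies_bouldin for m in models.values()],
            }
        ),
    }
    log.info("condition %s analysed: %d frames in %.1f s",
             spec.label, traj.n_frames, time.time() - t0)
    return out


def run_analysis(config: dict) -> dict:
    """Run the full condition-vs-control analysis from a config dict.

    Returns a report bundle: ``conditions`` (per-label results),
    ``differences`` (condition minus control products) and a ``manifest``
    (config hash, seed, version). Fails naming the stage on error;
    partial results computed so far are attached to the exception.
    """
    specs = _condition_specs(config)
    analysis = config.get("analysis", {})
    bundle: dict = {"conditions": {}, "differences": {}}
    control_label = None
    stage = "setup"
    try:
        for spec in specs:
            stage = f"load[{spec.label}]"
            traj = _load_trajectory(spec, config)
            stage = f"analyze[{spec.label}]"
            bundle["conditions"][spec.label] = _analyze_condition(spec, traj, analysis)
            if spec.role == "control":
                control_label = spec.label
        if control_label is not None:
            control = bundle["conditions"][control_label]
            for label, cond in bundle["conditions"].items():
                if label == control_label:
                    continue
                stage = f"difference[{label}]"
                bundle["differences"][label] = {
                    "sasa": sasa_difference(cond["sasa_matrix"], control["sasa_matrix"]),
                    "ramachandran": population_difference(
                        cond["ramachandran"], control["ramachandran"]
                    ),
                    "saltbridges": occupancy_difference(
                        cond["saltbridges"], control["saltbridges"]
                    ),
                    "table2": {
                        k: cond["table2"][k] - control["table2"][k]
                        for k in cond["table2"]
                    },
                }
    except Exception as exc:
        err = PipelineError(f"pipeline stage {stage!r} failed: {exc}")
        err.partial_bundle = bundle
        raise err from exc
    bundle["manifest"] = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.get("seed"),
        "version": __version__,
        "control": control_label,
    }
    return bundle


def write_report(bundle: dict, out_dir: str | Path) -> None:
    """Serialise a report bundle to CSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
    for label, cond in bundle["conditions"].items():
        d = out / label
        d.mkdir(exist_ok=True)
        pd.DataFrame(cond["table1"]).T.to_csv(d / "table1.csv")
        pd.Series(cond["table2"]).to_csv(d / "table2.csv", header=["percent"])
        (d / "ramachandran.json").write_text(json.dumps(cond["ramachandran"], indent=2))
        (d / "charges.json").write_text(json.dumps(cond["charges"], indent=2))
        cond["saltbridges"].matrix.to_csv(d / "saltbridges.csv")
        cond["sasa_matrix"].to_csv(d / "sasa_by_residue.csv")
        land = cond["landscape"]
        land["scan_table"].to_csv(d / "cluster_scan.csv", index=False)
        (d / "tica.json").write_text(json.dumps(land["tica"].as_dict(), indent=2))
        land["surface"].to_csv(d / "free_energy.csv")
        sel = land["models"][land["selected_k"]]
        pd.DataFrame({"frame": np.arange(len(sel.labels)),
                      "cluster": sel.labels}).to_csv(d / "clusters.csv", index=False)
    for label, diff in bundle["differences"].items():
        d = out / label
        np.savetxt(d / "sasa_difference.csv", diff["sasa"], delimiter=",")
        (d / "ramachandran_difference.json").write_text(
            json.dumps(diff["ramachandran"], indent=2)
        )
        diff["saltbridges"].to_csv(d / "saltbridge_difference.csv")


def crystal_checks(
    traj: Trajectory,
    first: int | None = None,
    last: int | None = None,
    pair: tuple[int, int] = (351, 386),
) -> dict[str, float]:
    """Reference distances from a crystallographic (or any single-frame)
    structure: the end-to-end Calpha distance of the construct and the
    Calpha separation of a named residue pair."""
    resids = traj.residue_numbers
    first = int(resids[0]) if first is None else first
    last = int(resids[-1]) if last is None else last
    sub = traj.select(resid_range=(first, last))
    ee = end_to_end(sub).values[0]
    out = {"ee_dist_nm": float(ee)}
    try:
        out[f"ca_{pair[0]}_{pair[1]}_nm"] = float(
            pair_distance(traj, pair[0], pair[1], "CA").values[0]
        )
    except KeyError:
        pass
    return out
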