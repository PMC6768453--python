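"""Configuration-driven execution of the analysis stages.

A pipeline config (dict, YAML or JSON) names an output directory and an
ordered subset of stages::

    stages: [synth, hsa, merge, parameterize, hydration-energy, uwham, report]

Each stage reads the files named in its own config block (or the outputs of
earlier stages), writes machine-readable artifacts into the output
directory, and contributes to the returned report dictionary.  A stage
failure raises :class:`PipelineError` naming the failing stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import alchemy, hsa, mapping, reporting, spheres, structure, synth

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline", "load_config"]

STAGES = ("synth", "hsa", "merge", "parameterize", "hydration-energy", "uwham", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def run_pipeline(config, seed: int = 0) -> dict:
    """Execute the configured stages and return the assembled report."""
    if not isinstance(config, dict):
        config = load_config(config)
    stages = config.get("stages", [])
    if not stages:
        raise ValueError("config must list at least one stage")
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", seed))

    report: dict = {"stages": list(stages), "seed": seed, "artifacts": {}}
    state: dict = {}
    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            _RUNNERS[stage](config.get(stage.replace("-", "_"), {}), outdir, seed,
                            state, report)
        except Exception as exc:  # noqa: BLE001 - report which stage failed
            raise PipelineError(stage, str(exc)) from exc
    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    report["artifacts"]["report"] = str(report_path)
    return report


def _stage_synth(cfg, outdir, seed, state, report):
    sites = [
        synth.PlantedSite(tuple(s["center"]), s["occupancy"],
                          tuple(s.get("e_sw", (-14.0, 1.0))),
                          tuple(s.get("e_ww", (-10.0, 1.0))),
                          s.get("jitter_sd", 0.3))
        for s in cfg.get("sites", [
            {"center": (0.0, 0.0, 0.0), "occupancy": 0.9},
            {"center": (3.5, 0.0, 0.0), "occupancy": 0.6},
        ])
    ]
    n_frames = int(cfg.get("n_frames", 2000))
    obs = synth.generate_water_frames(sites, n_frames, seed)
    waters_path = outdir / "waters.csv"
    hsa.write_water_csv(obs, waters_path)
    truth = {
        "n_frames": n_frames,
        "sites": [
            {"center": list(s.center), "occupancy": s.true_occupancy,
             "e_total": s.expected_e_total()}
            for s in sites
        ],
    }
    with open(outdir / "waters_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    state["waters"] = [str(waters_path)]
    state["n_frames"] = n_frames
    state["truth_sites"] = sites

    truth_g = synth.GaussianAlchemyTruth(
        mu=cfg.get("mu", -40.0), sigma=cfg.get("sigma", 3.0),
        temperature=cfg.get("temperature", 300.0))
    schedule = alchemy.LambdaSchedule.preset(cfg.get("schedule", "d3-28"))
    sample_set = synth.generate_lambda_samples(
        truth_g, schedule, int(cfg.get("n_per_state", 1000)), seed + 1)
    samples_path = outdir / "lambda_samples.csv"
    alchemy.write_samples_csv(sample_set, samples_path, outdir / "lambda_meta.json")
    state["samples"] = str(samples_path)
    state["samples_meta"] = str(outdir / "lambda_meta.json")
    state["alchemy_truth"] = truth_g
    report["artifacts"]["waters"] = str(waters_path)
    report["artifacts"]["lambda_samples"] = str(samples_path)


def _stage_hsa(cfg, outdir, seed, state, report):
    paths = cfg.get("waters", state.get("waters"))
    if not paths:
        raise ValueError("no water observation CSVs configured or generated")
    n_frames = int(cfg.get("n_frames", state.get("n_frames", 0)))
    if n_frames < 1:
        raise ValueError("n_frames must be provided")
    maps = []
    for i, p in enumerate(paths):
        obs = hsa.read_water_csv(p)
        config = hsa.ClusterConfig(
            n_frames=n_frames,
            region_center=tuple(cfg.get("region_center", (0.0, 0.0, 0.0))),
            region_radius=cfg.get("region_radius", 8.0),
            site_radius=cfg.get("site_radius", 1.0),
            min_occupancy=cfg.get("min_occupancy", 0.25),
            e_bulk=cfg.get("e_bulk", hsa.E_BULK_DEFAULT),
            e_total_convention=cfg.get("e_total_convention", "half-half"),
        )
        hmap = hsa.cluster_hydration_sites(obs, config, label=f"structure-{i}")
        hmap = hsa.compute_site_thermodynamics(hmap, obs)
        map_path = outdir / f"hydration_map_{i}.json"
        hsa.write_map_json(hmap, map_path)
        maps.append(hmap)
        report["artifacts"][f"hydration_map_{i}"] = str(map_path)
    state["maps"] = maps
    report["n_sites"] = [len(m) for m in maps]


def _stage_merge(cfg, outdir, seed, state, report):
    maps = state.get("maps")
    if maps is None:
        paths = cfg.get("maps")
        if not paths:
            raise ValueError("no hydration maps configured or generated")
        maps = [hsa.read_map_json(p) for p in paths]
    merged = mapping.merge_maps(maps, merge_radius=cfg.get("merge_radius", 2.0),
                                mode=cfg.get("mode", "contributing"))
    state["merged"] = merged
    merged_path = outdir / "merged_sites.json"
    with open(merged_path, "w") as fh:
        json.dump([asdict(m) for m in merged], fh, indent=1, default=float)
    report["artifacts"]["merged_sites"] = str(merged_path)
    report["n_merged_sites"] = len(merged)


def _stage_parameterize(cfg, outdir, seed, state, report):
    merged = state.get("merged")
    if merged is None:
        raise ValueError("merge stage must run before parameterize")
    assignments = mapping.group_nearby_sites(
        merged, group_radius=cfg.get("group_radius", 2.0))
    table = mapping.assignments_to_table(assignments)
    table_path = outdir / "sphere_assignments.csv"
    table.to_csv(table_path, index=False)
    sphere_list = [
        spheres.HydrationSphere(
            sphere_id=a.agbnp_site_id, h_s=a.h_s,
            center=tuple(np.mean([merged[i].center for i in a.source_hsa_ids], axis=0)),
            radius_rs=cfg.get("radius_rs", 1.4),
            switch_lo=cfg.get("switch_lo", 0.1),
            switch_hi=cfg.get("switch_hi", 0.5),
        )
        for a in assignments
    ]
    spheres_path = outdir / "spheres.json"
    spheres.write_spheres_json(sphere_list, spheres_path)
    state["spheres"] = sphere_list
    report["artifacts"]["sphere_assignments"] = str(table_path)
    report["artifacts"]["spheres"] = str(spheres_path)
    report["total_h_s"] = float(sum(a.h_s for a in assignments))


def _stage_hydration_energy(cfg, outdir, seed, state, report):
    sphere_list = state.get("spheres")
    if cfg.get("spheres"):
        sphere_list = spheres.read_spheres_json(cfg["spheres"])
    if sphere_list is None:
        raise ValueError("no hydration spheres configured or generated")
    if cfg.get("structure"):
        atoms = structure.load_structure(cfg["structure"])
        if cfg.get("ligand_sel"):
            atoms = atoms + structure.select_atoms(cfg["structure"], cfg["ligand_sel"])
    else:
        atoms = state.get("atoms", [])
    dg_hs, occ = spheres.enclosed_hydration_energy(
        sphere_list, atoms, grid_spacing=cfg.get("grid_spacing", 0.1))
    result = {
        "dG_hs": dg_hs,
        "per_sphere": [asdict(o) for o in occ],
    }
    path = outdir / "hydration_energy.json"
    with open(path, "w") as fh:
        json.dump(result, fh, indent=1, default=float)
    state["dG_hs"] = dg_hs
    report["artifacts"]["hydration_energy"] = str(path)
    report["dG_hs"] = dg_hs


def _stage_uwham(cfg, outdir, seed, state, report):
    samples_path = cfg.get("samples", state.get("samples"))
    if samples_path is None:
        raise ValueError("no lambda samples configured or generated")
    sample_set = alchemy.read_samples_csv(
        samples_path, metadata_path=cfg.get("metadata", state.get("samples_meta")))
    sample_set = sample_set.discard_initial(cfg.get("discard", 0.0))
    uw = alchemy.uwham_solve(sample_set)
    config = alchemy.TransferConfig(
        site_radius=cfg.get("site_radius", 3.5),
        standard_concentration=cfg.get("standard_concentration", 1.0),
        temperature=cfg.get("transfer_temperature", 298.15),
    )
    result = alchemy.decompose(sample_set, uw, config,
                               dG_ionization=cfg.get("dG_ionization", 0.0))
    payload = result.to_dict()
    payload["per_state_free_energies"] = uw.free_energies.tolist()
    payload["lambdas"] = uw.lambdas.tolist()
    payload["min_adjacent_overlap"] = float(
        min(uw.overlap[i, i + 1] for i in range(len(uw.lambdas) - 1)))
    path = outdir / "free_energy.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
    state["free_energy"] = result
    report["artifacts"]["free_energy"] = str(path)
    report["free_energy"] = result.to_dict()


def _stage_report(cfg, outdir, seed, state, report):
    import pandas as pd

    if cfg.get("experimental") and cfg.get("calculated"):
        records = reporting.read_experiment_csv(
            cfg["experimental"], temperature=cfg.get("temperature", 298.15))
        calc = pd.read_csv(cfg["calculated"])
        exp_by_id = {r.compound_id: r.dG_exp for r in records}
        pairs = [
            (exp_by_id[str(row.compound_id)], float(row.dG_calc))
            for row in calc.itertuples()
            if str(row.compound_id) in exp_by_id
        ]
        summary = reporting.accuracy_summary(pairs)
        report["accuracy"] = {
            "rmse": summary.rmse,
            "pearson_r": summary.pearson_r,
            "n": summary.n,
        }
    elif "free_energy" in state:
        report["accuracy"] = None
    else:
        raise ValueError("report stage needs experimental+calculated CSVs "
                         "or an upstream free-energy result")


_RUNNERS = {
    "synth": _stage_synth,
    "hsa": _stage_hsa,
    "merge": _stage_merge,
    "parameterize": _stage_parameterize,
    "hydration-energy": _stage_hydration_energy,
    "uwham": _stage_uwham,
    "report": _stage_report,
}
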