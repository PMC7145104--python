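"""Pipeline orchestration: config-driven stage execution with a run manifest.

Stage order: simulate (optional) -> qc -> panel (ancestral selection + LD
pruning) -> diversity (full and ancestral panels) -> permute -> distance ->
pca.  Every stage's parameters, locus/sample counts, and output checksums
are recorded in a JSON run manifest; all randomness flows from one master
seed through named substreams, so a rerun with the same config reproduces
every output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import AscPanelError, ConfigError
from .genotype_io import (
    GenotypeDataset,
    PopulationPartition,
    read_plink_text,
    read_population_table,
    write_plink_text,
)
from .qc import filter_loci
from .panel import PanelSelection, ld_prune, select_ancestral
from .diversity import population_diversity
from .permutation import results_to_tsv, run_permutation_test
from .distance_pca import (
    PopulationAlleleFrequencies,
    distance_matrix,
    export_distance,
    pca,
)
from .simulate import PopulationSpec, SimulationConfig, default_config, simulate_dataset

logger = logging.getLogger("ascpanel")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": None,          # dict of default_config overrides, or None
    "input": None,             # {ped, map, populations?}
    "qc": {"max_missing": 0.10, "min_maf": 0.01, "autosomes_only": True,
           "plink_compat": False},
    "panel": {"outgroups": None, "window_kb": 2000, "step": 10, "r2": 0.2},
    "diversity": {"f_reference": "pooled"},
    "permute": {"n_perm": 1000, "per_population": False},
    "distance": {"format": "nexus", "corrected": False, "panel": "ancestral"},
    "pca": {"components": 10, "panel": "ancestral"},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, params: dict, counts: dict, outputs: list[Path]) -> None:
        if any(s["name"] == name for s in self.stages):
            raise ConfigError(f"stage {name!r} recorded twice")
        self.stages.append(
            {
                "name": name,
                "params": params,
                "counts": counts,
                "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def load_config(path_or_dict) -> dict:
    """Load a YAML config and merge it over the defaults (shallow per stage)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config section {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def build_simulation_config(seed: int, overrides: dict | None) -> SimulationConfig:
    overrides = dict(overrides or {})
    if "populations" in overrides:
        overrides["populations"] = [
            PopulationSpec(**p) for p in overrides["populations"]
        ]
    return default_config(seed=seed, **overrides)


def run_pipeline(config, out_dir) -> RunManifest:
    """Execute the configured stages; write artifacts + manifest to out_dir."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(version=__version__, config_hash=cfg_hash, seed=seed)
    manifest_path = out / "manifest.json"

    current_stage = "setup"
    try:
        # -- inputs ------------------------------------------------------
        truth = None
        if cfg["simulate"] is not None or cfg["input"] is None:
            current_stage = "simulate"
            sim_cfg = build_simulation_config(seed, cfg["simulate"])
            genome, dataset, truth = simulate_dataset(sim_cfg)
            ped, mp = write_plink_text(dataset, out / "array")
            pops_tsv = out / "populations.tsv"
            with open(pops_tsv, "w") as fh:
                fh.write("sample_id\tpopulation_id\tgroup\n")
                groups = {p.population_id: p.group for p in sim_cfg.populations}
                for rec in dataset.samples.itertuples(index=False):
                    fh.write(f"{rec.sample_id}\t{rec.population_id}\t"
                             f"{groups[rec.population_id]}\n")
            truth_tsv = out / "truth.tsv"
            truth.to_tsv(truth_tsv)
            manifest.record(
                "simulate",
                {"seed": seed, "n_loci": sim_cfg.n_loci,
                 "discovery_maf_cutoff": sim_cfg.discovery_maf_cutoff},
                {"n_loci_genomewide": genome.n_loci, "n_loci_array": dataset.n_loci,
                 "n_samples": dataset.n_samples},
                [ped, mp, pops_tsv, truth_tsv],
            )
            partition = PopulationPartition(
                populations={p: list(np.flatnonzero(
                    dataset.samples["population_id"] == p))
                    for p in dict.fromkeys(dataset.samples["population_id"])},
                groups={p.population_id: p.group for p in sim_cfg.populations},
            )
            if cfg["panel"]["outgroups"] is None:
                cfg["panel"]["outgroups"] = [
                    p.population_id for p in sim_cfg.populations if p.group == "wild"
                ]
        else:
            current_stage = "input"
            inp = cfg["input"]
            dataset = read_plink_text(inp["ped"], inp["map"])
            if inp.get("populations"):
                partition = read_population_table(inp["populations"], dataset)
            else:
                partition = PopulationPartition.from_dataset(dataset)

        # -- qc ----------------------------------------------------------
        current_stage = "qc"
        q = cfg["qc"]
        dataset_qc, report = filter_loci(
            dataset,
            max_missing_frac=q["max_missing"],
            min_maf=q["min_maf"],
            autosomes_only=q["autosomes_only"],
            plink_compat=q["plink_compat"],
        )
        logger.info(report.summary())
        qc_tsv = out / "qc_report.tsv"
        report.to_tsv(qc_tsv)
        manifest.record("qc", dict(q),
                        {"n_input": report.n_input_loci, "n_retained": report.n_retained},
                        [qc_tsv])

        # -- panel -------------------------------------------------------
        current_stage = "panel"
        p = cfg["panel"]
        outgroups = p["outgroups"]
        if not outgroups:
            raise ConfigError(
                "panel stage needs outgroup population ids "
                "(config panel.outgroups, e.g. [BAN, GAU])"
            )
        anc_idx = select_ancestral(dataset_qc, partition, list(outgroups))
        if anc_idx.size == 0:
            raise AscPanelError("no loci polymorphic in the outgroups")
        pruned_idx = ld_prune(
            dataset_qc, window_kb=p["window_kb"], step_count=p["step"],
            r2_threshold=p["r2"], locus_subset=anc_idx,
        )
        lids = dataset_qc.loci["locus_id"]
        selection = PanelSelection(
            qc_pass=list(lids),
            ancestral=list(lids.iloc[anc_idx]),
            ld_pruned_retained=list(lids.iloc[pruned_idx]),
            params={"outgroups": list(outgroups), "window_kb": p["window_kb"],
                    "step_count": p["step"], "r2_threshold": p["r2"]},
        )
        panel_tsv = out / "panel.tsv"
        selection.to_tsv(panel_tsv)
        logger.info(
            "panel: %d QC-passed loci; %d ancestral; %d after LD pruning",
            len(selection.qc_pass), len(selection.ancestral),
            len(selection.ld_pruned_retained),
        )
        manifest.record("panel", selection.params,
                        {"n_qc_pass": len(selection.qc_pass),
                         "n_ancestral": len(selection.ancestral),
                         "n_pruned": len(selection.ld_pruned_retained)},
                        [panel_tsv])

        full_panel = np.arange(dataset_qc.n_loci)
        ancestral_panel = pruned_idx

        # -- diversity ---------------------------------------------------
        current_stage = "diversity"
        fref = cfg["diversity"]["f_reference"]
        outputs = []
        for label, subset in (("full", full_panel), ("ancestral", ancestral_panel)):
            table = population_diversity(dataset_qc, partition, subset, f_reference=fref)
            path = out / f"diversity_{label}.tsv"
            table.to_tsv(path)
            outputs.append(path)
        manifest.record("diversity", {"f_reference": fref},
                        {"n_full": int(full_panel.size),
                         "n_ancestral": int(ancestral_panel.size)},
                        outputs)

        # -- permutation -------------------------------------------------
        current_stage = "permute"
        n_perm = int(cfg["permute"]["n_perm"])
        per_pop = bool(cfg["permute"]["per_population"])
        results = run_permutation_test(
            dataset_qc, partition, full_panel, ancestral_panel,
            n_perm=n_perm, seed=seed, per_population=per_pop,
        )
        perm_tsv = out / "permutation.tsv"
        results_to_tsv(results, perm_tsv)
        manifest.record("permute",
                        {"n_perm": n_perm, "m": int(ancestral_panel.size),
                         "seed": seed, "per_population": per_pop},
                        {"n_populations": len(results)}, [perm_tsv])

        # -- distance ----------------------------------------------------
        current_stage = "distance"
        d = cfg["distance"]
        subset = ancestral_panel if d["panel"] == "ancestral" else full_panel
        freqs = PopulationAlleleFrequencies.from_dataset(dataset_qc, partition, subset)
        dmat = distance_matrix(freqs, corrected=d["corrected"])
        ext = "nex" if d["format"] == "nexus" else "phy"
        dist_path = out / f"reynolds.{ext}"
        export_distance(dmat, dist_path, format=d["format"])
        manifest.record("distance", dict(d), {"n_populations": len(dmat.labels)},
                        [dist_path])

        # -- pca ---------------------------------------------------------
        current_stage = "pca"
        pc = cfg["pca"]
        subset = ancestral_panel if pc["panel"] == "ancestral" else full_panel
        res = pca(dataset_qc, subset, n_components=int(pc["components"]))
        scores_tsv = out / "pca_scores.tsv"
        res.scores.to_csv(scores_tsv, sep="\t", index=False, float_format="%.6g")
        eig_tsv = out / "pca_eigenvalues.tsv"
        with open(eig_tsv, "w") as fh:
            fh.write("component\teigenvalue\tvariance_explained\n")
            for c, (e, v) in enumerate(zip(res.eigenvalues, res.variance_explained)):
                fh.write(f"PC{c + 1}\t{e:.6g}\t{v:.6g}\n")
        manifest.record("pca", dict(pc),
                        {"n_components": len(res.eigenvalues)},
                        [scores_tsv, eig_tsv])
    except Exception as exc:
        manifest.write(manifest_path)
        raise AscPanelError(f"pipeline failed in stage {current_stage!r}: {exc}") from exc

    manifest.write(manifest_path)
    return manifest
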