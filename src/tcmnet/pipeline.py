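"""End-to-end run: generate/load -> bipartite -> giant component -> project
-> communities -> coherence validation, with a machine-readable run report.

A run is fully described by a :class:`RunConfig` (which can be loaded from a
flat YAML key-value file); given the same config and seed, a rerun writes
byte-identical artifacts except for the timestamps recorded in the report.
Herb-side annotations (meridian, property) are validated against the herb
projection (NSN); ingredient-side annotations (smiles, target) against the
ingredient projection (ISN).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .bigraph import (
    build_bipartite,
    degree_stats,
    giant_component,
    load_incidence,
    project,
    write_projection,
)
from .community import PARTITIONERS, Partition
from .errors import ConfigError, RegistryError, TcmnetError
from .synthetic import ANNOTATION_KINDS, SyntheticConfig, generate_dataset, write_dataset
from .validation import AnnotationTable, validate

logger = logging.getLogger(__name__)

#: which projection each annotation kind validates against
KIND_SIDE = {"meridian": "herb", "property": "herb", "smiles": "ingredient", "target": "ingredient"}
SIDE_NAME = {"herb": "nsn", "ingredient": "isn"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``incidence_path`` (+ optional ``annotation_paths`` mapping name
    -> file) points at real input TSVs, or ``synthetic=True`` generates a
    planted-block dataset with ``synthetic_params`` overriding
    :class:`SyntheticConfig` defaults.
    """

    outdir: str = "tcmnet_run"
    seed: int = 0
    synthetic: bool = True
    synthetic_params: dict = field(default_factory=dict)
    incidence_path: str | None = None
    annotation_paths: dict = field(default_factory=dict)
    annotation_kinds: dict = field(default_factory=lambda: dict(ANNOTATION_KINDS))
    sides: list = field(default_factory=lambda: ["herb", "ingredient"])
    algorithm: str = "fast_greedy"
    weighted: bool = True
    similarity: dict = field(default_factory=dict)  # per-kind metric override
    n_replicates: int = 100

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written to disk).

    Artifacts land in ``config.outdir``: incidence.tsv, nsn.tsv, isn.tsv,
    nsn_partition.csv, isn_partition.csv, validation_<kind>.json,
    report.json.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return time.time()

    try:
        # -- input
        ts = stage("input")
        truth = None
        if config.synthetic:
            params = dict(config.synthetic_params)
            params.setdefault("seed", config.seed)
            syn = SyntheticConfig(**params)
            incidence, annotations, truth = generate_dataset(syn)
            write_dataset(incidence, annotations, truth, outdir)
        else:
            if not config.incidence_path:
                raise ConfigError("incidence_path required when synthetic is false")
            incidence = load_incidence(config.incidence_path)
            incidence.write(outdir / "incidence.tsv")
            annotations = {
                name: AnnotationTable.read(path, config.annotation_kinds[name])
                for name, path in config.annotation_paths.items()
            }
        report["stages"]["input"] = {
            "n_rows": len(incidence),
            "n_herbs": len(incidence.herbs),
            "n_ingredients": len(incidence.ingredients),
            "elapsed_s": round(time.time() - ts, 3),
        }

        # -- bipartite graph and giant component
        ts = stage("bipartite")
        bg = build_bipartite(incidence)
        report["stages"]["bipartite"] = {
            "n_nodes": bg.n_nodes,
            "n_edges": bg.n_edges,
            "elapsed_s": round(time.time() - ts, 3),
        }
        ts = stage("giant_component")
        gc = giant_component(bg)
        report["stages"]["giant_component"] = {
            "n_nodes": gc.n_nodes,
            "n_edges": gc.n_edges,
            "n_herbs": len(gc.side_a),
            "n_ingredients": len(gc.side_b),
            "elapsed_s": round(time.time() - ts, 3),
        }

        # -- projections, communities, validation
        if config.algorithm not in PARTITIONERS:
            raise RegistryError(f"unknown algorithm {config.algorithm!r}")
        partitioner = PARTITIONERS[config.algorithm]
        partitions: dict[str, Partition] = {}
        for side in config.sides:
            short = SIDE_NAME[side]
            ts = stage(f"project_{short}")
            pg = project(gc, side)
            write_projection(pg, outdir / f"{short}.tsv")
            _, mean_deg, het = degree_stats(pg)
            ts2 = stage(f"cluster_{short}")
            part = partitioner(pg) if config.weighted else partitioner(pg, weighted=False)
            part.write(outdir / f"{short}_partition.csv")
            partitions[side] = part
            entry = {
                "n_nodes": pg.number_of_nodes(),
                "n_edges": pg.number_of_edges(),
                "mean_degree": round(mean_deg, 6),
                "heterogeneity": round(het, 6),
                "n_communities": part.n_communities,
                "modularity": part.modularity,
                "elapsed_s": round(time.time() - ts, 3),
                "cluster_elapsed_s": round(time.time() - ts2, 3),
            }
            if truth is not None:
                block = truth.herb_block if side == "herb" else truth.ingredient_block
                nodes = sorted(part.assignment)
                entry["ari_vs_ground_truth"] = float(
                    adjusted_rand_score(
                        [block[n] for n in nodes], [part.assignment[n] for n in nodes]
                    )
                )
            report["stages"][f"projection_{short}"] = entry

        ts = stage("validation")
        report["validation"] = {}
        for name, ann in annotations.items():
            side = KIND_SIDE.get(name, "herb")
            if side not in partitions:
                continue
            rep = validate(
                partitions[side],
                ann,
                n_replicates=config.n_replicates,
                seed=config.seed,
                metric=config.similarity.get(name),
            )
            rep.write_json(outdir / f"validation_{name}.json")
            rep.write_values_tsv(outdir / f"validation_{name}_values.tsv")
            report["validation"][name] = {
                "side": SIDE_NAME[side],
                "metric": rep.metric,
                "observed_median": rep.observed_median,
                "null_median": rep.null_median,
                "p_value": rep.p_value,
                "n_clusters_evaluated": len(rep.observed),
                "n_unannotated": rep.n_unannotated,
            }
        report["stages"]["validation"] = {"elapsed_s": round(time.time() - ts, 3)}
    except TcmnetError as exc:
        exc.stage = report["stages"] and list(report["stages"])[-1]
        raise

    report["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    report["elapsed_s"] = round(time.time() - t0, 3)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
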