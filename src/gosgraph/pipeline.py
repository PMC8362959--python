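"""One-command orchestration: simulate (or load) -> priors -> cluster -> summarise.

A :class:`PipelineConfig` fully determines a run; the output directory
contains every intermediate table, the clustering, the summary surfaces, and
a ``provenance.json`` echoing the configuration, seeds and per-stage counts,
so any run can be reproduced or audited from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .annotations import AnnotationSet, build_label_space, build_prior_vectors
from .analysis import (
    order_profiles,
    posting_rate,
    propensity_matrix,
    render_outputs,
    respondent_profiles,
)
from .opinion_graph import read_survey, write_graphml, write_survey
from .sbm import infer
from .simulate import (
    SimulationConfig,
    preset_scenarios,
    simulate_annotators,
    simulate_survey,
)

__all__ = ["PipelineConfig", "run_pipeline", "compare_runs"]

log = logging.getLogger("gosgraph")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run (simulate or load)."""

    mode: str = "simulate"  # "simulate" | "load"
    preset: str | None = None
    simulation: SimulationConfig | None = None
    opinion_csv: str | None = None
    edge_csv: str | None = None
    respondent_csv: str | None = None
    annotation_csv: str | None = None
    use_priors: bool = True
    mass_on_labels: float = 0.99
    n_sweeps: int = 40
    n_restarts: int = 10
    seed: int = 0
    degree_corrected: bool = False
    n_propensity_rows: int | None = None  # pad with empty rows to align surveys
    out_dir: str = "gos_output"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate":
            if self.simulation is None and self.preset is None:
                raise ValueError("simulate mode needs a preset or a simulation config")
        else:
            if not (self.opinion_csv and self.edge_csv):
                raise ValueError("load mode needs opinion_csv and edge_csv")

    def resolved_simulation(self) -> SimulationConfig:
        assert self.mode == "simulate"
        sim = self.simulation or preset_scenarios(self.preset)  # type: ignore[arg-type]
        return dataclasses.replace(sim, seed=self.seed)

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("affinity", "archetype_weights", "display_size_law",
                        "group_categories"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(
                        tuple(x) if isinstance(x, list) else x for x in sim[key]
                    )
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the output directory.

    Stages: acquire graph (simulate or load) -> annotations -> prior vectors
    -> SBM inference -> posting rate, propensity matrix, palette profiles ->
    rendered outputs.  Identical configs produce identical numerical outputs.
    Errors carry the failing stage name; partial outputs are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    stage = "acquire-graph"
    try:
        ann = None
        truth = None
        if config.mode == "simulate":
            sim = config.resolved_simulation()
            graph, truth = simulate_survey(sim)
            rng_ann = np.random.default_rng(sim.seed + 1)
            ann = simulate_annotators(truth, sim, rng_ann)
            with open(out / "simulation_config.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump(dataclasses.asdict(sim), fh, sort_keys=False)
            rows = (
                [{"vertex_id": o, "kind": "opinion", "planted_label": g}
                 for o, g in truth.opinion_group_of.items()]
                + [{"vertex_id": r, "kind": "respondent", "planted_label": a}
                   for r, a in truth.archetype_of.items()]
            )
            pd.DataFrame(rows).to_csv(out / "ground_truth.csv", index=False)
            provenance["stages"][stage] = {
                "n_opinions": graph.n_opinions,
                "n_respondents": graph.n_respondents,
                "n_edges": graph.n_edges,
                "n_rejected": len(truth.rejected),
            }
        else:
            graph = read_survey(config.edge_csv, config.opinion_csv, config.respondent_csv)
            if config.annotation_csv:
                ann = AnnotationSet.from_csv(config.annotation_csv)
            provenance["stages"][stage] = {
                "n_opinions": graph.n_opinions,
                "n_respondents": graph.n_respondents,
                "n_edges": graph.n_edges,
            }
        log.info("%s: %s", stage, provenance["stages"][stage])
        write_survey(
            graph, out / "opinions.csv", out / "edges.csv", out / "respondents.csv"
        )
        write_graphml(graph, out / "graph.graphml")

        stage = "priors"
        priors = None
        if ann is not None:
            ann.to_csv(out / "annotations.csv")
        if config.use_priors and ann is not None and len(ann) > 0:
            space = build_label_space(ann)
            priors = build_prior_vectors(
                ann, space, config.mass_on_labels, opinion_ids=graph.opinions
            )
            priors.to_csv(out / "priors.csv")
            provenance["stages"][stage] = {"K": space.K, "n_annotated": len(ann.opinion_ids)}
            log.info("priors: K=%d", space.K)

        stage = "inference"
        part, bd = infer(
            graph,
            priors=priors,
            n_sweeps=config.n_sweeps,
            n_restarts=config.n_restarts,
            seed=config.seed,
            degree_corrected=config.degree_corrected,
        )
        rows = [
            {"vertex_id": v, "kind": "opinion" if v in graph.opinions else "respondent",
             "group": g}
            for v, g in part.group_of.items()
        ]
        pd.DataFrame(rows).to_csv(out / "partition.csv", index=False)
        with open(out / "objective.json", "w", encoding="utf-8") as fh:
            json.dump(bd.as_dict(), fh, indent=2)
        provenance["stages"][stage] = {"B": part.B, "total_nats": bd.total}
        log.info("inference: B=%d total=%.2f nats", part.B, bd.total)

        stage = "analysis"
        rate = posting_rate(graph)
        matrix = propensity_matrix(graph, part, n_rows=config.n_propensity_rows)
        if priors is not None:
            from .sbm import group_annotation_labels

            names = group_annotation_labels(graph, part, priors)
            enriched = []
            for lab in matrix.row_labels:
                gid = int(lab[1:]) if lab[1:].isdigit() else None
                enriched.append(f"{lab}:{names[gid]}" if gid in names else lab)
            matrix.row_labels = enriched
        palette = respondent_profiles(graph, part)
        ordering, obj = order_profiles(palette, seed=config.seed)
        palette.ordering = ordering
        palette.objective_value = obj
        render_outputs(matrix, palette, out)
        provenance["stages"][stage] = {
            "posting_authors": rate.authors,
            "posting_total": rate.total,
            "posting_percentage": rate.percentage,
            "seriation_objective": obj,
            "flagged_columns": matrix.flagged_columns,
            "excluded_respondents": len(palette.excluded),
        }
        log.info("analysis: posting %.1f%%, seriation objective %.3f",
                 rate.percentage, obj)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        provenance["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    return out


def compare_runs(dir_a: str | Path, dir_b: str | Path) -> dict:
    """Compare two completed runs: partition ARI and propensity-table distance.

    The report is symmetric; comparing a directory with itself yields ARI 1
    and distance 0.  Missing files produce explicit report entries instead of
    errors.
    """
    dir_a, dir_b = Path(dir_a), Path(dir_b)
    report: dict = {"dir_a": str(dir_a), "dir_b": str(dir_b)}

    pa, pb = dir_a / "partition.csv", dir_b / "partition.csv"
    if not pa.exists() or not pb.exists():
        report["partition"] = {"status": f"missing: {[p.name for p in (pa, pb) if not p.exists()]}"}
    else:
        a = pd.read_csv(pa).set_index("vertex_id")
        b = pd.read_csv(pb).set_index("vertex_id")
        common = a.index.intersection(b.index)
        entry: dict = {"status": "ok", "n_common": int(len(common))}
        for kind in ("opinion", "respondent"):
            ids = [v for v in common if a.loc[v, "kind"] == kind]
            if ids:
                entry[f"ari_{kind}"] = float(
                    adjusted_rand_score(a.loc[ids, "group"], b.loc[ids, "group"])
                )
            entry[f"n_{kind}_groups_a"] = int(
                a.loc[a["kind"] == kind, "group"].nunique()
            )
            entry[f"n_{kind}_groups_b"] = int(
                b.loc[b["kind"] == kind, "group"].nunique()
            )
        if len(common):
            entry["ari_all"] = float(
                adjusted_rand_score(a.loc[common, "group"], b.loc[common, "group"])
            )
        entry["n_groups_a"] = int(a["group"].nunique())
        entry["n_groups_b"] = int(b["group"].nunique())
        report["partition"] = entry

    ma, mb = dir_a / "propensity.csv", dir_b / "propensity.csv"
    if not ma.exists() or not mb.exists():
        report["propensity"] = {
            "status": f"missing: {[p.name for p in (ma, mb) if not p.exists()]}"
        }
    else:
        A = pd.read_csv(ma, index_col=0)
        B = pd.read_csv(mb, index_col=0)
        if A.shape == B.shape:
            report["propensity"] = {
                "status": "ok",
                "max_abs_difference": float(np.abs(A.to_numpy() - B.to_numpy()).max())
                if A.size else 0.0,
            }
        else:
            report["propensity"] = {
                "status": "shape mismatch",
                "shape_a": list(A.shape),
                "shape_b": list(B.shape),
            }
    return report
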