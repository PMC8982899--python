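"""Whole-workflow orchestration with an artifact manifest.

``run_all`` drives the full chain -- (a) network inference per condition,
(b) differential networks, (c) OMU system with mean GRmax, (d) drug OMU
vectors, (e) balance-point selection and the linear model, (f) combined
vectors and their ILRs, (g) GIS, (h) DGIS, (i) the ranked candidate list --
writing every intermediate artifact into an output directory and recording a
manifest (parameters, seed, stage timings, SHA-256 checksums) so reruns are
verifiable.  Deterministic stages rerun with the same seed produce identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as io
from .model import PipelineOptions, SynergyModel
from .simulate import StudyConfig, generate_dose_response, generate_study

logger = logging.getLogger("omu_synergy")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_run_config(path) -> dict:
    """YAML run configuration: a 'study' block (simulate) or explicit input
    paths, plus an 'options' block mirroring PipelineOptions fields."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise io.FormatError("run config must be a YAML mapping")
    return cfg


def options_from_dict(d: dict) -> PipelineOptions:
    fields = {f.name for f in dataclasses.fields(PipelineOptions)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown option(s): {sorted(unknown)}")
    d = dict(d)
    if "centroid_bounds" in d:
        d["centroid_bounds"] = tuple(d["centroid_bounds"])
    return PipelineOptions(**d)


def run_all(config: dict, out_dir) -> dict:
    """Execute the pipeline per a run-config dict; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    options = options_from_dict(config.get("options", {}))
    manifest: dict = {
        "seed": options.seed,
        "options": dataclasses.asdict(options),
        "stages": [],
        "artifacts": {},
    }

    def record(stage: str, t0: float, *paths: Path) -> None:
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})
        for p in paths:
            manifest["artifacts"][p.name] = _sha256(p)

    try:
        stage = "inputs"
        t0 = time.time()
        if "study" in config:
            study_cfg = StudyConfig(**{**config["study"], "seed": options.seed})
            study = generate_study(study_cfg)
            expr, prior, ppi, gr = (study.expression, study.prior, study.ppi,
                                    study.gr_table)
            control_id = study_cfg.control_id
            io.write_expression(out / "expression.tsv", expr)
            io.write_edge_list(out / "prior.tsv", prior)
            io.write_edge_list(out / "ppi.tsv", ppi)
            io.write_gr_table(out / "gr.csv", gr)
            record("simulate", t0, out / "expression.tsv", out / "prior.tsv",
                   out / "ppi.tsv", out / "gr.csv")
        else:
            inputs = config["inputs"]
            expr = io.read_expression(inputs["expression"])
            prior = io.read_edge_list(inputs["prior"])
            ppi = io.read_edge_list(inputs["ppi"], symmetric=True)
            gr = io.read_gr_table(inputs["gr"])
            control_id = inputs.get("control_id", "control")
            record("inputs", t0)

        stage = "fit"
        t0 = time.time()
        model = SynergyModel(expr, prior, ppi, gr, control_id=control_id,
                             options=options)
        results = model.fit()
        record("fit", t0)

        stage = "networks"
        t0 = time.time()
        grn_dir = out / "grns"
        grn_dir.mkdir(exist_ok=True)
        for cond, grn in results.grns.items():
            pd.DataFrame(grn.weights, index=grn.tf_ids, columns=grn.gene_ids).to_csv(
                grn_dir / f"grn_{cond}.tsv", sep="\t", float_format=io.FLOAT_FMT,
                index_label="tf",
            )
        record("networks", t0, *sorted(grn_dir.glob("grn_*.tsv")))

        stage = "modules"
        t0 = time.time()
        modules_path = out / "modules.json"
        io.write_json(modules_path, {
            s: [m.to_dict() for m in mods]
            for s, mods in results.modules_by_sample.items()
        })
        record("modules", t0, modules_path)

        stage = "omu_system"
        t0 = time.time()
        system_path = out / "omu_system.json"
        io.write_json(system_path, results.omu_system.to_dict())
        vec_rows = [
            {"sample": s, "omu_id": results.omu_system.omus[i].omu_id,
             "value": v.values[i]}
            for s, v in sorted(results.vectors.items())
            for i in np.nonzero(v.values)[0]
        ]
        vectors_path = out / "omu_vectors.tsv"
        pd.DataFrame(vec_rows).to_csv(vectors_path, sep="\t", index=False,
                                      float_format=io.FLOAT_FMT)
        record("omu_system", t0, system_path, vectors_path)

        stage = "model"
        t0 = time.time()
        model_path = out / "model.json"
        io.write_json(model_path, {
            **results.linear_model.to_dict(),
            "balances": results.ilrs,
            "excluded": sorted(set(results.vectors) - set(results.ilrs)),
        })
        record("model", t0, model_path)

        stage = "ranking"
        t0 = time.time()
        ranking_path = out / "ranking.tsv"
        io.write_ranking(ranking_path, results.ranking.drop(columns=["rank"]))
        top_path = out / "top_candidates.tsv"
        io.write_ranking(top_path, results.top.drop(columns=["rank"]))
        record("ranking", t0, ranking_path, top_path)

        if "study" in config:
            stage = "dose_response"
            t0 = time.time()
            top_pairs = [tuple(sorted((r.drug_1, r.drug_2)))
                         for r in results.top.itertuples()]
            matrices = generate_dose_response(study_cfg, gr, pairs=top_pairs)
            from .doseresponse import zip_synergy
            zip_rows = []
            for (d1, d2), mat in sorted(matrices.items()):
                zr = zip_synergy(mat)
                zip_rows.append({"drug_1": d1, "drug_2": d2,
                                 "zip": zr.zip_score, "synergy": zr.synergy_call})
            zip_path = out / "zip_scores.tsv"
            pd.DataFrame(zip_rows).to_csv(zip_path, sep="\t", index=False,
                                          float_format=io.FLOAT_FMT)
            record("dose_response", t0, zip_path)

            stage = "enrichment"
            t0 = time.time()
            from .enrichment import joint_binomial_mle, n_pairs
            n_all = n_pairs(len(gr))
            rng = np.random.default_rng(options.seed)
            n_rand = max(1, round(0.1 * n_all))
            all_pairs = [tuple(sorted((a, b)))
                         for i, a in enumerate(sorted(gr.drugs()))
                         for b in sorted(gr.drugs())[i + 1:]]
            rand_pairs = [all_pairs[i] for i in
                          rng.choice(n_all, size=n_rand, replace=False)]
            rand_mats = generate_dose_response(study_cfg, gr, pairs=rand_pairs)
            k1 = sum(zip_synergy(m).synergy_call for m in matrices.values())
            k2 = sum(zip_synergy(m).synergy_call for m in rand_mats.values())
            enr = joint_binomial_mle(k1, len(matrices), k2, len(rand_mats),
                                     finite_population=n_all)
            enrich_path = out / "enrichment.json"
            io.write_json(enrich_path, enr.to_dict())
            record("enrichment", t0, enrich_path)

        stage = "summary"
        t0 = time.time()
        summary_path = out / "summary.txt"
        summary_path.write_text(results.summary() + "\n")
        record("summary", t0, summary_path)
    except Exception:
        manifest["failed_stage"] = stage
        io.write_json(out / "manifest.json", manifest)
        logger.error("run_all aborted at stage %r; partial manifest preserved", stage)
        raise

    io.write_json(out / "manifest.json", manifest)
    return manifest
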