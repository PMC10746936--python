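"""End-to-end orchestration: DEG meta-analysis → differential network →
modules → optional prognostics, repurposing and text mining, driven by a
single YAML/JSON config and producing a manifest for exact re-runs."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deg import (
    consensus_directions,
    differential_expression,
    intersect_common_degs,
    ora_fisher,
    write_deg_table,
)
from .diffcoexp import DifferentialCoexpressionModel
from .io import read_expression_matrix, read_gene_sets, write_gene_sets
from .repurpose import (
    build_module_signature,
    read_corpus,
    read_drug_library,
    reversal_score,
    tfidf_novelty,
)
from .survival import evaluate_prognostic_module, read_survival_table

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "alpha": 0.05,
    "fc_threshold": 2.0,
    "epsilon": 0.5,
    "min_module_size": 5,
    "density_threshold": 0.5,
    "top_k": 50,
}


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            config = json.load(fh)
        else:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    return config


def _resolve_thresholds(config: dict) -> dict:
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(config.get("thresholds", {}))
    if not 0 < thresholds["alpha"] < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if thresholds["epsilon"] < 0:
        raise ValueError("epsilon must be non-negative")
    return thresholds


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the configured stages and return (and write) a run manifest.

    Config keys: ``studies`` (list of {matrix, labels}), ``thresholds``,
    optional ``gene_sets`` (GMT for ORA), ``survival`` ({table,
    matrix/labels or reuse of a study, stratify_by_stage}), ``repurpose``
    ({library}), ``textmine`` ({corpus, drugs}), ``outdir``, ``seed``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config.get("outdir", "dicoexnet_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = _resolve_thresholds(config)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "tool": "dicoexnet",
        "version": __version__,
        "seed": seed,
        "thresholds": thresholds,
        "inputs": config.get("studies", []),
        "stages": {},
        "outputs": {},
    }

    # --- ingest -----------------------------------------------------------
    try:
        studies = [
            read_expression_matrix(
                s["matrix"], s["labels"], study_id=s.get("study_id")
            )
            for s in config["studies"]
        ]
        if len(studies) < 2:
            raise ValueError("pipeline needs at least two studies")
    except Exception as exc:  # noqa: BLE001 - re-tagged
        raise PipelineError("ingest", exc) from exc

    # --- per-study DEGs and intersection ---------------------------------
    try:
        deg_tables = []
        for study in studies:
            table = differential_expression(
                study, alpha=thresholds["alpha"],
                fc_threshold=thresholds["fc_threshold"],
            )
            out = outdir / f"degs_{study.study_id}.tsv"
            write_deg_table(table, out)
            deg_tables.append(table)
            manifest["outputs"][f"degs_{study.study_id}"] = str(out)
        common = sorted(intersect_common_degs(deg_tables))
        (outdir / "common_degs.txt").write_text("\n".join(common) + "\n")
        manifest["outputs"]["common_degs"] = str(outdir / "common_degs.txt")
        manifest["stages"]["deg"] = {
            "per_study_counts": [len(t) for t in deg_tables],
            "n_common": len(common),
        }
        if not common:
            raise ValueError("no common DEGs across studies")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("deg", exc) from exc

    # --- optional ORA -----------------------------------------------------
    if "gene_sets" in config:
        try:
            collection = read_gene_sets(config["gene_sets"])
            universe = set().union(*(set(s.genes) for s in studies))
            ora = ora_fisher(
                set(common) & universe, universe, collection,
                alpha=thresholds["alpha"],
            )
            out = outdir / "ora.tsv"
            ora.to_csv(out, sep="\t", index=False)
            manifest["outputs"]["ora"] = str(out)
            manifest["stages"]["ora"] = {
                "n_sets": len(collection),
                "n_significant": int(ora["significant"].sum()),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("ora", exc) from exc

    # --- differential co-expression network and modules ------------------
    try:
        model = DifferentialCoexpressionModel(
            studies, genes=common,
            epsilon=thresholds["epsilon"],
            min_module_size=thresholds["min_module_size"],
            density_threshold=thresholds["density_threshold"],
        )
        results = model.fit()
        results.to_graphml(outdir / "network.graphml")
        results.to_sif(outdir / "network.sif")
        results.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        results.modules_table().to_csv(
            outdir / "modules.tsv", sep="\t", index=False
        )
        if results.modules:
            results.modules_to_gmt(outdir / "modules.gmt")
            manifest["outputs"]["modules_gmt"] = str(outdir / "modules.gmt")
        (outdir / "summary.txt").write_text(results.summary() + "\n")
        manifest["outputs"].update(
            {
                "network_graphml": str(outdir / "network.graphml"),
                "network_sif": str(outdir / "network.sif"),
                "pairs": str(outdir / "pairs.tsv"),
                "modules": str(outdir / "modules.tsv"),
                "summary": str(outdir / "summary.txt"),
            }
        )
        manifest["stages"]["coexpress"] = {
            "pcritic_disease": results.pcritic_d.value,
            "pcritic_control": results.pcritic_h.value,
            "n_pairs": int(len(results.pairs)),
            "n_modules": len(results.modules),
            "modules": [
                {
                    "module_id": m.module_id, "n_nodes": m.n_nodes,
                    "n_edges": m.n_edges, "density": m.density,
                }
                for m in results.modules
            ],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("coexpress", exc) from exc

    top_module = results.modules[0] if results.modules else None

    # --- optional prognostics --------------------------------------------
    if "survival" in config and top_module is not None:
        try:
            sconf = config["survival"]
            table = read_survival_table(sconf["table"])
            study = read_expression_matrix(
                sconf["matrix"], sconf["labels"], validate=False
            ) if "matrix" in sconf else studies[0]
            report = evaluate_prognostic_module(
                table, list(top_module.nodes), study,
                stratify_by_stage=bool(sconf.get("stratify_by_stage", False)),
                alpha=thresholds["alpha"],
            )
            report.to_json(outdir / "prognostic_report.json")
            manifest["outputs"]["prognostic_report"] = str(
                outdir / "prognostic_report.json"
            )
            manifest["stages"]["survival"] = report.as_dict()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("survival", exc) from exc

    # --- optional repurposing and text mining ----------------------------
    signature = None
    if top_module is not None:
        merged = pd.concat(deg_tables).drop_duplicates("gene", keep="first")
        directions = consensus_directions(deg_tables, merged["gene"])
        merged = merged.set_index("gene")
        merged["direction"] = directions
        signature = build_module_signature(
            list(top_module.nodes), merged.reset_index()
        )
        signature.to_json(outdir / "signature.json")
        manifest["outputs"]["signature"] = str(outdir / "signature.json")

    if "repurpose" in config and signature is not None:
        try:
            library = read_drug_library(config["repurpose"]["library"])
            ranking = reversal_score(
                signature, library, top_k=int(thresholds["top_k"])
            )
            ranking.to_csv(outdir / "drug_ranking.tsv", sep="\t", index=False)
            manifest["outputs"]["drug_ranking"] = str(outdir / "drug_ranking.tsv")
            manifest["stages"]["repurpose"] = {
                "n_drugs_scored": int(len(ranking)),
                "top_drug": str(ranking.iloc[0]["drug"]),
                "top_score": float(ranking.iloc[0]["score"]),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("repurpose", exc) from exc

    if "textmine" in config:
        try:
            tconf = config["textmine"]
            corpus = read_corpus(tconf["corpus"])
            drugs = [
                line.strip()
                for line in Path(tconf["drugs"]).read_text().splitlines()
                if line.strip()
            ]
            novelty = tfidf_novelty(drugs, corpus)
            novelty.to_csv(outdir / "novelty.tsv", sep="\t", index=False)
            manifest["outputs"]["novelty"] = str(outdir / "novelty.tsv")
            manifest["stages"]["textmine"] = {
                "n_drugs": len(drugs),
                "n_novel": int(
                    novelty.drop_duplicates("drug")["novel"].sum()
                ),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("textmine", exc) from exc

    # outputs are recorded relative to outdir so that re-runs in different
    # locations produce identical manifests
    manifest["outputs"] = {
        key: str(Path(value).relative_to(outdir))
        for key, value in manifest["outputs"].items()
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = manifest_path.name
    manifest["outdir"] = str(outdir)
    logger.info("pipeline finished; manifest at %s", manifest_path)
    return manifest


def write_simulated_inputs(config_obj, outdir: str | Path) -> dict:
    """Materialize a synthetic experiment on disk and return its file map.

    Writes matrices/labels per study, survival table, drug library, corpus,
    drug-name list and the ground-truth JSON, plus a ready-to-run pipeline
    config.
    """
    from .io import write_expression_matrix
    from .repurpose import write_corpus
    from .simulate import (
        NOVEL_DRUG_NAMES,
        simulate_corpus_and_library,
        simulate_multistudy_expression,
        simulate_validation_cohort,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    studies, truth = simulate_multistudy_expression(config_obj)
    file_map: dict = {"studies": []}
    for study in studies:
        matrix = outdir / f"{study.study_id}_matrix.tsv"
        labels = outdir / f"{study.study_id}_labels.tsv"
        write_expression_matrix(study, matrix, labels)
        file_map["studies"].append(
            {"matrix": str(matrix), "labels": str(labels),
             "study_id": study.study_id}
        )
    cohort, surv = simulate_validation_cohort(config_obj)
    write_expression_matrix(
        cohort, outdir / "validation_matrix.tsv", outdir / "validation_labels.tsv"
    )
    surv.reset_index().to_csv(outdir / "survival.tsv", sep="\t", index=False)
    corpus, library, info = simulate_corpus_and_library(truth)
    write_corpus(corpus, outdir / "abstracts.jsonl")
    rows = [
        {"drug": drug, "gene": gene, "weight": weight}
        for drug, weights in library.items()
        for gene, weight in weights.items()
    ]
    pd.DataFrame(rows).to_csv(outdir / "drug_library.tsv", sep="\t", index=False)
    drug_names = [info["reverser"], *info["known_drugs"], *NOVEL_DRUG_NAMES]
    (outdir / "drugs.txt").write_text("\n".join(drug_names) + "\n")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.as_dict(), fh, indent=2)
    file_map.update(
        {
            "survival": str(outdir / "survival.tsv"),
            "validation_matrix": str(outdir / "validation_matrix.tsv"),
            "validation_labels": str(outdir / "validation_labels.tsv"),
            "corpus": str(outdir / "abstracts.jsonl"),
            "library": str(outdir / "drug_library.tsv"),
            "drugs": str(outdir / "drugs.txt"),
            "ground_truth": str(outdir / "ground_truth.json"),
        }
    )
    pipeline_config = {
        "studies": file_map["studies"],
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "survival": {
            "table": file_map["survival"],
            "matrix": file_map["validation_matrix"],
            "labels": file_map["validation_labels"],
            "stratify_by_stage": True,
        },
        "repurpose": {"library": file_map["library"]},
        "textmine": {"corpus": file_map["corpus"], "drugs": file_map["drugs"]},
        "seed": config_obj.seed,
        "outdir": str(outdir / "results"),
    }
    with open(outdir / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(pipeline_config, fh, sort_keys=False)
    file_map["pipeline_config"] = str(outdir / "pipeline.yaml")
    return file_map
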