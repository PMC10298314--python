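"""End-to-end driver: expression -> activity -> pairs -> screen -> subtypes
-> hubs -> risk model -> evaluation, with every intermediate written out.

A run is described by one YAML/dict config naming either input files
(expression, metadata, GMT) or a simulation block, plus per-stage options.
All randomness derives from the single top-level seed.  Outputs are plain
TSV/JSON; the run log records parameters and package version (its timestamp
is the only non-deterministic byte in a run).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .activity import ssgsea_matrix
from .evaluate import auc
from .io import read_expression, read_gmt, write_expression, write_gmt, write_model
from .network import build_graph, hub_subnetwork, mcc_rank
from .pairs import build_mpp, differential_screen
from .scoring import TrainConfig, risk_score, train_mppss
from .simulate import SimulationConfig, generate_dataset
from .subtype import consensus_cluster, exp_transform, metrics_frame, select_rank

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "validate_config"]

_STAGES = ("inputs", "activity", "pairs", "screen", "subtype", "hubs", "train", "evaluate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_config(config: dict) -> dict:
    if ("simulation" in config) == ("inputs" in config):
        raise ValueError(
            "config must name exactly one of 'simulation' or 'inputs' "
            "(expression/metadata/gmt paths)"
        )
    if "inputs" in config:
        missing = {"expression", "metadata", "gmt"} - set(config["inputs"])
        if missing:
            raise ValueError(f"inputs block missing keys: {sorted(missing)}")
    return config


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run every stage and write artifacts under ``out_dir``; returns it."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: dict = {"seed": seed, "version": __version__, "config": _jsonable(config)}
    t0 = time.time()

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("inputs")
        if "simulation" in config:
            sim = dict(config["simulation"])
            sim.setdefault("seed", seed)
            if "genes_per_pathway" in sim:
                sim["genes_per_pathway"] = tuple(sim["genes_per_pathway"])
            sim_cfg = SimulationConfig(**sim)
            expr, catalog, truth = generate_dataset(sim_cfg)
            write_expression(expr, out / "expression.tsv", out / "metadata.tsv")
            write_gmt(catalog, out / "pathways.gmt")
            with open(out / "truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        else:
            paths = config["inputs"]
            expr = read_expression(paths["expression"], paths["metadata"])
            catalog = read_gmt(paths["gmt"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("inputs", e) from e

    try:
        stage("activity")
        act_cfg = config.get("activity", {})
        activity = ssgsea_matrix(
            expr, catalog,
            alpha=act_cfg.get("alpha", 0.25),
            normalize=act_cfg.get("normalize", True),
            min_genes=act_cfg.get("min_genes", 2),
        )
        activity.scores.to_csv(out / "activity.tsv", sep="\t", index_label="pathway")
    except Exception as e:
        raise PipelineError("activity", e) from e

    try:
        stage("pairs")
        mpp = build_mpp(activity)
        mpp.delta.to_csv(out / "mpp_delta.tsv", sep="\t")
        mpp.indicator.to_csv(out / "mpp_indicator.tsv", sep="\t")
    except Exception as e:
        raise PipelineError("pairs", e) from e

    scr_cfg = config.get("screen", {})
    positive = scr_cfg.get("positive", "AD")
    try:
        stage("screen")
        screen = differential_screen(
            mpp, expr.groups,
            alpha_adj=scr_cfg.get("alpha_adj", 0.01),
            positive=positive,
        )
        screen.to_frame().to_csv(out / "pairs.tsv", sep="\t", index=False)
        log["screen"] = {
            "tested": len(screen.results),
            "skipped": len(screen.skipped),
            "flagged": len(screen.flagged),
        }
    except Exception as e:
        raise PipelineError("screen", e) from e

    flagged = screen.flagged_pair_ids

    sub_cfg = config.get("subtype", {})
    try:
        stage("subtype")
        case_ids = expr.groups.index[expr.groups == positive]
        if flagged:
            rep = sub_cfg.get("representation", "continuous")
            V = pd.DataFrame(
                exp_transform(mpp.values_for(rep).loc[flagged, case_ids]),
                index=flagged, columns=case_ids,
            )
            k_range = range(sub_cfg.get("k_min", 2), sub_cfg.get("k_max", 6) + 1)
            results = consensus_cluster(
                V, k_range=k_range, nrun=sub_cfg.get("nrun", 10), seed=seed,
            )
            k = select_rank(results)
            chosen = results[k]
            metrics_frame(results).to_csv(out / "subtype_metrics.tsv", sep="\t")
            chosen.consensus.to_csv(out / "consensus.tsv", sep="\t")
            chosen.assignments.map(lambda c: f"S{c}").to_csv(
                out / "subtypes.tsv", sep="\t", index_label="sample"
            )
            log["subtype"] = {"k": k, **{m: v for m, v in chosen.metrics().items() if m != "k"}}
        else:
            logger.warning("no flagged pairs; skipping subtype stage")
            log["subtype"] = {"skipped": "no flagged pairs"}
    except Exception as e:
        raise PipelineError("subtype", e) from e

    try:
        stage("hubs")
        graph = build_graph(flagged)
        ranking = mcc_rank(graph)
        pd.DataFrame(ranking, columns=["pathway", "mcc"]).to_csv(
            out / "hubs.tsv", sep="\t", index=False
        )
        if ranking:
            sub = hub_subnetwork(graph, ranking, top_n=config.get("hubs", {}).get("top_n", 10))
            log["hubs"] = {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges(),
                           "subnetwork_nodes": sub.number_of_nodes()}
        else:
            log["hubs"] = {"nodes": 0, "edges": 0}
    except Exception as e:
        raise PipelineError("hubs", e) from e

    tr_cfg = config.get("train", {})
    try:
        stage("train")
        feature_pairs = flagged if flagged else mpp.pair_index.tolist()
        sub_mpp = mpp.values_for(tr_cfg.get("representation", "continuous")).loc[feature_pairs]
        tcfg = TrainConfig(
            train_frac=tr_cfg.get("train_frac", 0.7),
            n_iter=tr_cfg.get("n_iter", 1000),
            cv_folds=tr_cfg.get("cv_folds", 10),
            freq_threshold=tr_cfg.get("freq_threshold", 0.8),
            representation=tr_cfg.get("representation", "continuous"),
            positive=positive,
        )

        class _Sub:
            def values_for(self, representation):
                return sub_mpp

        report = train_mppss(_Sub(), expr.groups, tcfg, seed=seed)
        write_model(report.model, out / "model.json")
        report.frequencies.to_csv(out / "selection_frequencies.tsv", sep="\t")
        log["train"] = {
            "selected": report.selected,
            "n_train": len(report.train_samples),
            "n_test": len(report.test_samples),
            **report.metrics,
        }
    except Exception as e:
        raise PipelineError("train", e) from e

    try:
        stage("evaluate")
        if report.model.entries:
            scores = risk_score(report.model, mpp)
            scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample")
            y = expr.groups == positive
            test = scores.loc[report.test_samples]
            roc = auc(test, y.loc[report.test_samples])
            log["evaluate"] = {
                "test_auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                "n_pos": roc.n_pos, "n_neg": roc.n_neg,
            }
        else:
            logger.warning("empty model; skipping evaluation")
            log["evaluate"] = {"skipped": "empty model"}
    except Exception as e:
        raise PipelineError("evaluate", e) from e

    log["elapsed_seconds"] = round(time.time() - t0, 3)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
    with open(out / "summary.txt", "w") as fh:
        fh.write(_summary_text(log))
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _summary_text(log: dict) -> str:
    lines = [f"pathpair run (seed {log['seed']}, version {log['version']})"]
    if "screen" in log:
        s = log["screen"]
        lines.append(
            f"screen: {s['tested']} pairs tested, {s['skipped']} skipped, "
            f"{s['flagged']} flagged"
        )
    if "subtype" in log and "k" in log.get("subtype", {}):
        m = log["subtype"]
        lines.append(
            f"subtype: k={m['k']} (cophenetic {m['cophenetic']:.3f}, "
            f"dispersion {m['dispersion']:.3f})"
        )
    if "train" in log and "test_auc" in log.get("train", {}):
        lines.append(
            f"model: {len(log['train']['selected'])} pairs selected, "
            f"train AUC {log['train']['train_auc']:.3f}, "
            f"test AUC {log['train']['test_auc']:.3f}"
        )
    if "evaluate" in log and "test_auc" in log.get("evaluate", {}):
        e = log["evaluate"]
        lines.append(
            f"held-out AUC {e['test_auc']:.3f} "
            f"(95% CI {e['ci_low']:.3f}-{e['ci_high']:.3f})"
        )
    return "\n".join(lines) + "\n"
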