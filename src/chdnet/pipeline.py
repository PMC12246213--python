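"""End-to-end orchestration: simulate/load -> impute -> screen -> learn ->
estimate -> classify -> report, driven by a single config mapping with every
source of randomness seeded, plus network export in JSON / DOT / GraphML.

A run writes its outputs under ``output_dir`` and finishes by atomically
writing a manifest (config hash, stage timings, output paths, warnings), so
any run is reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import __version__
from .cohort import (
    CohortMatrix,
    collinearity_screen,
    knn_impute,
    read_cohort_matrix,
    read_roles_sidecar,
    variable_frequencies,
    write_cohort_matrix,
)
from .classify import FylerMatrix, evaluate, predict_assign, train_classifier
from .inference import FittedNetwork, fit_cpts
from .risk import RiskQuery, bootstrap_risk, screen_features, write_report
from .simulate import (
    FylerScenario,
    ScenarioConfig,
    generate_fyler_cohort,
    simulate_cohort,
)
from .structure import learn_exact, moralize


class PipelineError(ValueError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    completed: bool = False

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def export_network(fn: FittedNetwork, path, fmt: str = "json",
                   moralized: bool = False) -> None:
    """Write a fitted network as JSON (always with CPTs), DOT or GraphML
    (moralized-undirected when requested, directed otherwise)."""
    path = Path(path)
    if fmt == "json":
        path.write_text(fn.to_json())
        return
    if fmt == "dot":
        lines = []
        if moralized:
            g = moralize(fn.dag)
            lines.append("graph network {")
            lines += [f'  "{v}";' for v in fn.dag.nodes]
            lines += [f'  "{a}" -- "{b}";' for a, b in sorted(g.edges())]
        else:
            lines.append("digraph network {")
            lines += [f'  "{v}";' for v in fn.dag.nodes]
            lines += [f'  "{a}" -> "{b}";' for a, b in fn.dag.edges]
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return
    if fmt == "graphml":
        g = moralize(fn.dag) if moralized else fn.dag.to_networkx()
        nx.write_graphml(g, path)
        return
    raise PipelineError(f"unknown export format {fmt!r}")


def run_pipeline(config: dict | str | os.PathLike) -> RunManifest:
    """Execute the configured stages in order; see the package docs for the
    config schema. Any stage may be omitted; missing inputs fail before any
    stage runs."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("output_dir", "chdnet_run"))
    manifest = RunManifest(_config_hash(config), __version__, seed)

    # validate inputs up front
    if "input" in config:
        cohort_path = Path(config["input"]["cohort"])
        if not cohort_path.exists():
            raise PipelineError(f"input cohort {cohort_path} does not exist")
    elif "scenario" not in config:
        raise PipelineError("config needs either 'scenario' or 'input'")
    for net_name, net in config.get("networks", {}).items():
        if "variables" not in net:
            raise PipelineError(f"network {net_name!r} lists no variables")

    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        t0 = time.perf_counter()

        def done(**outputs):
            manifest.stages.append(
                {"stage": name,
                 "seconds": round(time.perf_counter() - t0, 3)})
            manifest.outputs.update(outputs)
        return done

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cohort = _stage_cohort(config, seed, out_dir, stage)
        cohort = _stage_impute(config, cohort, out_dir, stage)
        _stage_screen(config, cohort, seed, out_dir, stage)
        _stage_networks(config, cohort, seed, out_dir, stage)
        _stage_classify(config, seed, out_dir, stage)
    manifest.warnings = [str(w.message) for w in caught]
    manifest.completed = True
    tmp = out_dir / "manifest.json.tmp"
    tmp.write_text(manifest.to_json())
    tmp.replace(out_dir / "manifest.json")
    return manifest


def _stage_cohort(config, seed, out_dir, stage) -> CohortMatrix:
    done = stage("cohort")
    if "input" in config:
        inp = config["input"]
        roles = (read_roles_sidecar(inp["roles"]) if "roles" in inp else None)
        cohort = read_cohort_matrix(inp["cohort"], roles=roles)
        done(cohort=str(inp["cohort"]))
        return cohort
    sc = config["scenario"]
    cfg = ScenarioConfig(
        n_patients=int(sc.get("n_patients", 2253)),
        seed=seed,
        missing_rate=float(sc.get("missing_rate", 0.05)),
        scenario=sc.get("name", "pcgc_like"),
    )
    cohort = simulate_cohort(cfg)
    path = out_dir / "cohort.tsv"
    write_cohort_matrix(cohort, path)
    freq_path = out_dir / "baseline_frequencies.tsv"
    variable_frequencies(cohort).to_csv(freq_path, sep="\t")
    done(cohort=str(path), baseline_frequencies=str(freq_path))
    return cohort


def _stage_impute(config, cohort, out_dir, stage) -> CohortMatrix:
    if cohort.is_complete:
        return cohort
    done = stage("impute")
    k = int(config.get("impute", {}).get("k", 10))
    imputed = knn_impute(cohort, k=k)
    path = out_dir / "cohort_imputed.tsv"
    write_cohort_matrix(imputed, path)
    done(cohort_imputed=str(path))
    return imputed


def _stage_screen(config, cohort, seed, out_dir, stage) -> None:
    sc = config.get("screen")
    if not sc:
        return
    done = stage("screen")
    table = screen_features(
        cohort, list(sc["candidates"]), list(sc["targets"]),
        B=int(sc.get("B", 1000)), seed=seed,
        smoothing=sc.get("smoothing", 0.01),
    )
    path = out_dir / "feature_screen.tsv"
    table.to_csv(path, sep="\t", index=False)
    done(feature_screen=str(path))


def _stage_networks(config, cohort, seed, out_dir, stage) -> None:
    nets = config.get("networks", {})
    for name, net in nets.items():
        done = stage(f"network:{name}")
        variables = list(net["variables"])
        sub = cohort.subset(variables)
        corr = collinearity_screen(sub, threshold=net.get(
            "collinearity_threshold", 0.9))
        corr.phi.to_csv(out_dir / f"{name}_phi.tsv", sep="\t")
        dag = learn_exact(sub, max_parents=net.get("max_parents"))
        fn = fit_cpts(dag, sub, smoothing=net.get("smoothing", 0.01))
        export_network(fn, out_dir / f"{name}.json", "json")
        export_network(fn, out_dir / f"{name}_moral.dot", "dot",
                       moralized=True)
        outputs = {f"network_{name}": str(out_dir / f"{name}.json")}
        estimates = []
        for q in net.get("queries", []):
            rq = RiskQuery(q["kind"],
                           {k: int(v) for k, v in q["targets"].items()},
                           q["factor"], int(q.get("factor_value", 1)))
            estimates.append(bootstrap_risk(
                cohort, variables, rq,
                B=int(net.get("B", 1000)),
                seed=seed,
                summary=net.get("summary", "percentile_median"),
                smoothing=net.get("smoothing", 0.01),
            ))
        if estimates:
            rpath = out_dir / f"{name}_risk.tsv"
            write_report(estimates, rpath)
            outputs[f"risk_{name}"] = str(rpath)
        done(**outputs)


def _stage_classify(config, seed, out_dir, stage) -> None:
    cc = config.get("classify")
    if not cc:
        return
    done = stage("classify")
    fs = FylerScenario(mixing=float(cc.get("mixing", 0.05)))
    frame, labels = generate_fyler_cohort(
        fs, int(cc.get("n_patients", 3000)), seed)
    fm = FylerMatrix(frame)
    model = train_classifier(
        fm, labels, folds=int(cc.get("folds", 5)),
        grid=cc.get("grid"), seed=seed,
    )
    preds = predict_assign(model, fm)
    metrics = evaluate(labels, preds)
    preds.to_csv(out_dir / "classifier_predictions.tsv", sep="\t")
    metrics["per_class"].to_csv(out_dir / "classifier_per_class.tsv",
                                sep="\t")
    summary = {
        "overall_accuracy": metrics["overall_accuracy"],
        "macro": metrics["macro"],
        "hyperparameters": model.hyperparameters,
    }
    (out_dir / "classifier_summary.json").write_text(
        json.dumps(summary, indent=2))
    done(classifier_predictions=str(out_dir / "classifier_predictions.tsv"),
         classifier_summary=str(out_dir / "classifier_summary.json"))
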