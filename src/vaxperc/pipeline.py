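"""End-to-end orchestration: survey -> clusters -> word graphs -> transition
evidence -> model structure -> dynamics.

A single YAML/dict config with sections ``data``, ``prep``, ``cluster``,
``graphs``, ``rules`` and ``dynamics`` (any section omittable) drives the
four-stage chain. The report collects the config snapshot, cluster summary
(with ARI against planted labels when present), per-question top-k tables,
graph edge summaries, the transition-evidence table, the validated model
structure and any requested dynamics results; rebuilding it from the same
config is bit-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import dynamics, resources, subpop_cluster, transition_map, word_graph
from .synthetic_survey import SurveyDataset, generate_survey_dataset, schema_from_config
from .text_prep import TokenizedCorpus

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    config: dict
    cluster_summary: dict = field(default_factory=dict)
    top_k: Dict[str, List] = field(default_factory=dict)
    graph_edges: Dict[str, dict] = field(default_factory=dict)
    evidence: Optional[pd.DataFrame] = None
    structure: Optional[transition_map.ModelStructure] = None
    dynamics_results: dict = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "cluster_summary": self.cluster_summary,
            "top_k": self.top_k,
            "graph_edges": self.graph_edges,
            "evidence": (self.evidence.to_dict(orient="records")
                         if self.evidence is not None else None),
            "structure": (self.structure.to_dict()
                          if self.structure is not None else None),
            "dynamics": self.dynamics_results,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    def to_markdown(self) -> str:
        lines = ["# Vaccine-perception pipeline report", ""]
        if self.cluster_summary:
            lines += ["## Subpopulations", ""]
            for key, val in sorted(self.cluster_summary.items()):
                lines.append(f"- {key}: {val}")
            lines.append("")
        if self.top_k:
            lines += ["## Top-k words per open question", ""]
            for q, ranking in self.top_k.items():
                words = ", ".join(f"{w} ({f:.3f})" for w, f in ranking)
                lines.append(f"- {q}: {words}")
            lines.append("")
        if self.evidence is not None:
            lines += ["## Transition evidence", "",
                      self.evidence.to_string(index=False), ""]
        if self.dynamics_results:
            lines += ["## Dynamics", ""]
            for key, val in self.dynamics_results.items():
                lines.append(f"- {key}: {val}")
            lines.append("")
        return "\n".join(lines)


def _stage(timings: dict, name: str, start: float) -> float:
    now = time.perf_counter()
    timings[name] = round(now - start, 6)
    return now


def run_pipeline(config: Optional[dict] = None) -> PipelineReport:
    """Execute the full chain on a synthetic or CSV-loaded survey."""
    if config is None:
        config = {}
    report = PipelineReport(config=config)
    t0 = time.perf_counter()

    # --- data ------------------------------------------------------------
    data_cfg = config.get("data", {}) or {}
    survey_cfg = resources.default_survey_config()
    survey_cfg.update(data_cfg.get("survey", {}))
    if "csv" in data_cfg:
        schema = schema_from_config(survey_cfg)
        dataset = SurveyDataset.from_csv(data_cfg["csv"], schema)
    else:
        dataset = generate_survey_dataset(survey_cfg)
    t0 = _stage(report.timings, "data", t0)

    # --- clustering ------------------------------------------------------
    cl_cfg = config.get("cluster", {}) or {}
    label_qs = survey_cfg.get("label_questions", {})
    assignment = subpop_cluster.cluster_dataset(
        dataset,
        cut=cl_cfg.get("cut", 4),
        willingness_question=label_qs.get("willingness", "Q3"),
        vaccinated_question=label_qs.get("vaccinated", "Q2"),
    )
    counts = pd.Series(assignment.clusters).value_counts().sort_index()
    summary = {"n_respondents": int(len(dataset.table)),
               "n_clusters": int(assignment.n_clusters()),
               "cluster_sizes": {int(k): int(v) for k, v in counts.items()}}
    if assignment.labels:
        summary["labels"] = {int(k): v
                             for k, v in sorted(assignment.labels.items())}
    planted = dataset.planted_labels
    if planted is not None:
        summary["ari_vs_planted"] = float(
            adjusted_rand_score(planted, assignment.clusters))
    report.cluster_summary = summary
    t0 = _stage(report.timings, "cluster", t0)

    # --- text prep + word graphs ----------------------------------------
    g_cfg = config.get("graphs", {}) or {}
    k = int(g_cfg.get("k", 6))
    prep_cfg = config.get("prep", {}) or {}
    lemmatize_tokens = bool(prep_cfg.get("lemmatize", True))
    graphs_by_question: Dict[str, list] = {}
    for q in dataset.open_questions():
        corpus = TokenizedCorpus.from_answers(
            q, dataset.open_answers(q), lemmatize_tokens=lemmatize_tokens)
        freq = word_graph.term_frequencies(corpus)
        if freq.empty:
            continue
        bag = word_graph.select_top_k(freq, k=k, question=q)
        report.top_k[q] = bag.ranking
        gs = []
        for cls in ("noun", "verb"):
            G = word_graph.build_association_graph(corpus, bag, cls)
            word_graph.annotate_polarity(G)
            gs.append(G)
            report.graph_edges[f"{q}:{cls}"] = {
                "n_nodes": G.number_of_nodes(),
                "n_edges": G.number_of_edges(),
            }
        graphs_by_question[q] = gs
    t0 = _stage(report.timings, "graphs", t0)

    # --- transition rules ------------------------------------------------
    rules_cfg = config.get("rules", {}) or {}
    if "file" in rules_cfg:
        import yaml
        with open(rules_cfg["file"], "r", encoding="utf-8") as fh:
            templates = yaml.safe_load(fh)["rules"]
        rules = transition_map.compile_rules(templates)
    else:
        rules = transition_map.compile_rules()
    report.evidence = transition_map.match_transitions(graphs_by_question, rules)
    report.structure = transition_map.build_model_graph(rules)
    t0 = _stage(report.timings, "rules", t0)

    # --- dynamics (optional) ---------------------------------------------
    dyn_cfg = config.get("dynamics")
    if dyn_cfg:
        params = dynamics.ModelParameters.reference(
            **{k_: float(v) for k_, v in (dyn_cfg.get("params") or {}).items()})
        eqs = dynamics.find_equilibria(params)
        report.dynamics_results["equilibria"] = [
            {"u": round(eq.u, 6), "h": round(eq.h, 6), "w": round(eq.w, 6),
             "v": round(eq.v, 6), "stability": eq.stability,
             "branch": eq.branch_tag}
            for eq in eqs
        ]
        scan_cfg = dyn_cfg.get("scan")
        if scan_cfg:
            grid = np.linspace(float(scan_cfg["from"]), float(scan_cfg["to"]),
                               int(scan_cfg.get("steps", 50)))
            scans = dynamics.continuation_branch(
                params, scan_cfg.get("vary", "f"), grid,
                direction=scan_cfg.get("direction", "both"))
            report.dynamics_results["scan"] = {
                direction: scan.regimes
                for direction, scan in scans.items()
            }
            report.dynamics_results["bistable_anywhere"] = any(
                "bistable" in scan.regimes for scan in scans.values())
        _stage(report.timings, "dynamics", t0)
    return report
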