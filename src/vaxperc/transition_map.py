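"""Compile word-graph evidence into the compartmental transition structure.

Transition rules are data, not code: a declarative YAML resource lists, for
each arrow of the model graph, its source and target compartment, whether it
is autonomous or induced (and by whom), the rate symbol(s) it binds, and the
word co-locations that evidence it. The default resource transcribes the
survey findings: eight arrows among U (unwilling), H (hesitant), W (willing)
and V (vaccinated), plus birth/death demography mu.

``match_transitions`` checks each rule's evidence pairs against the
word-association graphs (exact unordered edge match after normalization);
``build_model_graph`` validates that the compiled arrows bind every rate
symbol of the dynamical system exactly once, and ``symbolic_rhs`` rebuilds
the ODE right-hand side from the rules so structure and equations can be
machine-checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd
import sympy as sp
import yaml

from . import resources

__all__ = [
    "TransitionRule",
    "ModelStructure",
    "compile_rules",
    "match_transitions",
    "build_model_graph",
    "symbolic_rhs",
]

COMPARTMENTS = ("U", "H", "W", "V")
RATE_SYMBOLS = frozenset({"beta", "eta", "k", "g", "e", "f", "d", "r", "c", "b"})
_VALID_INDUCERS = {"W", "V", "availability", "self"}


class StructureError(ValueError):
    """Raised when a rule set violates the model-structure contract."""


@dataclass(frozen=True)
class TransitionRule:
    """One arrow of the compartmental model with its survey evidence."""

    source: str
    target: str
    kind: str                          # "autonomous" | "induced"
    inducers: Tuple[str, ...]
    rate_form: str                     # "constant" | "mass_action" | "saturating"
    params: Tuple[str, ...]
    evidence: Tuple[Tuple[str, str], ...] = ()
    question: Optional[str] = None

    def __post_init__(self):
        if self.source not in ("U", "H", "W"):
            raise StructureError(f"illegal source {self.source!r}")
        if self.target not in COMPARTMENTS:
            raise StructureError(f"illegal target {self.target!r}")
        if self.source == self.target:
            raise StructureError("source equals target")
        bad = set(self.inducers) - _VALID_INDUCERS
        if bad:
            raise StructureError(f"unknown inducers {bad}")
        if self.kind == "induced" and not self.inducers:
            raise StructureError("induced rule without inducers")
        if self.kind == "autonomous" and set(self.inducers) - {"self", "availability"}:
            raise StructureError("autonomous rule with compartment inducers")
        if self.rate_form == "mass_action" and len(self.params) != len(self.inducers):
            raise StructureError("mass-action rule needs one symbol per inducer")
        if self.rate_form == "saturating" and len(self.params) != 2:
            raise StructureError("saturating rule binds (throughput, half-saturation)")
        unknown = set(self.params) - RATE_SYMBOLS
        if unknown:
            raise StructureError(f"unknown parameter symbols {unknown}")


@dataclass
class ModelStructure:
    """The four compartments, their arrows, and demography."""

    rules: List[TransitionRule]
    demography_symbol: str = "mu"
    compartments: Tuple[str, ...] = COMPARTMENTS

    def to_graph(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.add_nodes_from(self.compartments)
        for rule in self.rules:
            label = ",".join(rule.params)
            if G.has_edge(rule.source, rule.target):
                G[rule.source][rule.target]["params"] += "," + label
            else:
                G.add_edge(rule.source, rule.target, params=label,
                           kinds=rule.kind)
        return G

    def to_dict(self) -> dict:
        return {
            "demography": self.demography_symbol,
            "compartments": list(self.compartments),
            "rules": [
                {
                    "source": r.source, "target": r.target, "kind": r.kind,
                    "inducers": list(r.inducers), "rate_form": r.rate_form,
                    "params": list(r.params),
                    "evidence": [list(p) for p in r.evidence],
                    "question": r.question,
                }
                for r in self.rules
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelStructure":
        rules = compile_rules(data["rules"])
        return build_model_graph(rules,
                                 demography_symbol=data.get("demography", "mu"))

    @classmethod
    def from_yaml(cls, text: str) -> "ModelStructure":
        return cls.from_dict(yaml.safe_load(text))


def compile_rules(rule_templates: Optional[Sequence[Mapping]] = None
                  ) -> List[TransitionRule]:
    """Validate declarative rule templates into ``TransitionRule`` objects.

    ``None`` loads the shipped default (the transcription of the survey's
    transition tables: 8 rules). Duplicate parameter symbols across rules
    are rejected.
    """
    if rule_templates is None:
        rule_templates = resources.transition_rule_templates()
    rules = []
    seen_params: Dict[str, int] = {}
    for i, t in enumerate(rule_templates):
        rule = TransitionRule(
            source=str(t["source"]),
            target=str(t["target"]),
            kind=str(t["kind"]),
            inducers=tuple(str(x) for x in t.get("inducers", ())),
            rate_form=str(t.get("rate_form", "constant")),
            params=tuple(str(p) for p in t["params"]),
            evidence=tuple((str(a), str(b)) for a, b in t.get("evidence", ())),
            question=t.get("question"),
        )
        for p in rule.params:
            if p in seen_params:
                raise StructureError(
                    f"parameter {p!r} bound by rules {seen_params[p]} and {i}")
            seen_params[p] = i
        rules.append(rule)
    return rules


def match_transitions(graphs: Mapping[str, Iterable[nx.Graph]],
                      rules: Sequence[TransitionRule]) -> pd.DataFrame:
    """Evidence report: which co-locations of each rule appear as edges.

    ``graphs`` maps question id -> iterable of association graphs (noun and
    verb). Evidence pairs are matched unordered against the union of edge
    sets; a rule is supported when at least one of its pairs is found.
    Absence is reported, never raised.
    """
    edge_index: Dict[str, Dict[FrozenSet[str], int]] = {}
    for q, gs in graphs.items():
        idx: Dict[FrozenSet[str], int] = {}
        for G in gs:
            for a, b, data in G.edges(data=True):
                key = frozenset((a, b))
                idx[key] = idx.get(key, 0) + int(data.get("count", 1))
        edge_index[q] = idx
    rows = []
    for i, rule in enumerate(rules):
        idx = edge_index.get(rule.question or "", {})
        found = []
        counts = []
        for pair in rule.evidence:
            c = idx.get(frozenset(pair), 0)
            if c > 0:
                found.append(pair)
                counts.append(c)
        rows.append({
            "rule": i,
            "transition": f"{rule.source}->{rule.target}",
            "kind": rule.kind,
            "params": ",".join(rule.params),
            "question": rule.question,
            "n_evidence": len(rule.evidence),
            "n_found": len(found),
            "found": "; ".join(f"({a},{b})x{c}" for (a, b), c in zip(found, counts)),
            "supported": len(found) > 0,
        })
    return pd.DataFrame(rows)


def build_model_graph(rules: Sequence[TransitionRule],
                      demography_symbol: str = "mu") -> ModelStructure:
    """Assemble and validate the full model structure.

    Every rate symbol of the dynamical system must be bound by exactly one
    rule; V must have no outgoing arrow (vaccination is absorbing up to
    demography).
    """
    bound = [p for r in rules for p in r.params]
    if len(bound) != len(set(bound)):
        dupes = {p for p in bound if bound.count(p) > 1}
        raise StructureError(f"parameters bound more than once: {sorted(dupes)}")
    missing = RATE_SYMBOLS - set(bound)
    if missing:
        raise StructureError(f"unbound parameter symbols: {sorted(missing)}")
    return ModelStructure(rules=list(rules), demography_symbol=demography_symbol)


def symbolic_rhs(structure: ModelStructure) -> Tuple[sp.Expr, sp.Expr, sp.Expr, sp.Expr]:
    """Rebuild the ODE right-hand side symbolically from the rule set.

    Each rule contributes a signed term pair (outflow from its source,
    inflow to its target): a constant-rate arrow gives p*x_source, a
    mass-action arrow gives p*x_source*x_inducer per inducer, and the
    saturating supply arrow gives c*w/(b+w). Demography adds mu births into
    U and mu deaths from every compartment. Comparing the result with the
    hand-written equations machine-checks structure/equation consistency.
    """
    u, h, w, v = sp.symbols("u h w v", nonnegative=True)
    state = {"U": u, "H": h, "W": w, "V": v}
    syms = {name: sp.Symbol(name, positive=True)
            for name in list(RATE_SYMBOLS) + [structure.demography_symbol]}
    flows = {comp: sp.Integer(0) for comp in COMPARTMENTS}
    for rule in structure.rules:
        x_src = state[rule.source]
        if rule.rate_form == "constant":
            term = syms[rule.params[0]] * x_src
        elif rule.rate_form == "mass_action":
            term = sum(syms[p] * x_src * state[ind]
                       for p, ind in zip(rule.params, rule.inducers))
        elif rule.rate_form == "saturating":
            c_sym, b_sym = (syms[p] for p in rule.params)
            term = c_sym * x_src / (b_sym + x_src)
        else:
            raise StructureError(f"unknown rate form {rule.rate_form!r}")
        flows[rule.source] -= term
        flows[rule.target] += term
    mu = syms[structure.demography_symbol]
    flows["U"] += mu
    for comp in COMPARTMENTS:
        flows[comp] -= mu * state[comp]
    return tuple(sp.simplify(flows[cmp]) for cmp in COMPARTMENTS)
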