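"""Multi-valued logical models: rules, fixed points, attractors, reduction, edits.

A model assigns one rule per network node.  Signaling nodes are Boolean
(levels 0/1); the two phenotype output nodes (and, after refinement,
selected nodes such as a forkhead-family node) are multi-valued with
levels 0..max_level.  A regulator counts as *active* in any Boolean
context when its level is >= 1.

Rule conventions for the generic model derived from a signed network:

* all activators are joined by OR, all inhibitors by OR, and the two
  clauses are combined with the *link operator* AND NOT (inhibitors
  dominate) or, where overridden, OR NOT (activation favored);
* a node with no regulators keeps its own value (identity rule), so the
  topology admits both resting and stimulated interpretations until
  baseline data pins it;
* each output node carries a counting rule: its level is the number of
  active positive regulators minus active negative regulators, clipped
  to [0, max_level].

Fixed points are enumerated exactly: a feedback vertex set of the
regulatory dependency graph is enumerated over all level combinations and
the remainder (an acyclic subgraph) is filled in by propagation; an
assignment is kept iff every enumerated node reproduces its value.
Asynchronous attractors are the terminal strongly connected components of
the explicit one-node-per-step transition graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx

from .expr import (Const, Expr, ExprError, Var, conj, disj, negate, parse_expr)
from .network import RegulatoryNetwork, make_network

AND_NOT = "and_not"
OR_NOT = "or_not"

State = dict  # node -> int level


class ModelError(ValueError):
    pass


def is_active(level: int) -> bool:
    return level >= 1


# ---------------------------------------------------------------------------
# rules


class Rule:
    """Base class; a rule computes the target's next level from a state."""

    target: str

    @property
    def regulators(self) -> frozenset[str]:
        raise NotImplementedError

    def next_value(self, state: State) -> int:
        raise NotImplementedError

    def expr(self) -> Expr:
        """Boolean abstraction of the rule (level >= 1), used for substitution."""
        raise NotImplementedError

    def substitute(self, name: str, expression: Expr) -> "Rule":
        raise NotImplementedError


@dataclass(frozen=True)
class LinkRule(Rule):
    """(A1|...|Ak) AND-NOT/OR-NOT (I1|...|Im) structured rule."""

    target: str
    activators: tuple[str, ...]
    inhibitors: tuple[str, ...]
    operator: str = AND_NOT

    def __post_init__(self):
        if self.operator not in (AND_NOT, OR_NOT):
            raise ModelError(f"unknown link operator {self.operator!r}")
        if not self.activators and not self.inhibitors:
            raise ModelError(f"{self.target}: link rule needs at least one regulator")
        object.__setattr__(self, "activators", tuple(sorted(set(self.activators))))
        object.__setattr__(self, "inhibitors", tuple(sorted(set(self.inhibitors))))

    @property
    def regulators(self):
        return frozenset(self.activators) | frozenset(self.inhibitors)

    def next_value(self, state):
        act = any(state[a] >= 1 for a in self.activators)
        inh = any(state[i] >= 1 for i in self.inhibitors)
        if not self.inhibitors:
            return int(act)
        if not self.activators:
            return int(not inh)
        if self.operator == AND_NOT:
            return int(act and not inh)
        return int(act or not inh)

    def expr(self):
        act = disj([Var(a) for a in self.activators]) if self.activators else None
        inh = disj([Var(i) for i in self.inhibitors]) if self.inhibitors else None
        if inh is None:
            return act
        if act is None:
            return negate(inh)
        if self.operator == AND_NOT:
            return conj([act, negate(inh)])
        return disj([act, negate(inh)])

    def substitute(self, name, expression):
        if name not in self.regulators:
            return self
        return ExprRule(self.target, self.expr().substitute({name: expression}))


@dataclass(frozen=True)
class IdentityRule(Rule):
    """Input node: next value equals the current value."""

    target: str

    @property
    def regulators(self):
        return frozenset((self.target,))

    def next_value(self, state):
        return state[self.target]

    def expr(self):
        return Var(self.target)

    def substitute(self, name, expression):
        return self  # self-loop; never eliminated


@dataclass(frozen=True)
class ConstantRule(Rule):
    target: str
    value: int = 0

    @property
    def regulators(self):
        return frozenset()

    def next_value(self, state):
        return self.value

    def expr(self):
        return Const(self.value >= 1)

    def substitute(self, name, expression):
        return self


@dataclass(frozen=True)
class ExprRule(Rule):
    """Free Boolean expression over regulators."""

    target: str
    expression: Expr

    @property
    def regulators(self):
        return self.expression.variables()

    def next_value(self, state):
        return int(self.expression.evaluate(lambda n: state[n] >= 1))

    def expr(self):
        return self.expression

    def substitute(self, name, expression):
        if name not in self.regulators:
            return self
        return ExprRule(self.target, self.expression.substitute({name: expression}))


@dataclass(frozen=True)
class CountingRule(Rule):
    """Multi-level rule: clip(#active positives - #active negatives, 0, max_level).

    Members are expressions (plain variables for an unreduced model) so
    that model reduction can substitute eliminated regulators.
    """

    target: str
    positives: tuple[Expr, ...]
    negatives: tuple[Expr, ...] = ()
    max_level: int = 3
    count_mode: str = "net"  # "net" or "positive"

    @property
    def regulators(self):
        regs: set[str] = set()
        for e in self.positives + self.negatives:
            regs |= e.variables()
        return frozenset(regs)

    def next_value(self, state):
        active = lambda n: state[n] >= 1
        pos = sum(1 for e in self.positives if e.evaluate(active))
        if self.count_mode == "positive":
            raw = pos
        else:
            raw = pos - sum(1 for e in self.negatives if e.evaluate(active))
        return max(0, min(self.max_level, raw))

    def expr(self):
        raise ModelError(f"{self.target}: counting rules have no Boolean substitution form")

    def substitute(self, name, expression):
        if name not in self.regulators:
            return self
        sub = {name: expression}
        return replace(self,
                       positives=tuple(e.substitute(sub) for e in self.positives),
                       negatives=tuple(e.substitute(sub) for e in self.negatives))


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class LogicalModel:
    network: RegulatoryNetwork
    rules: dict  # node -> Rule
    max_levels: dict  # node -> int
    edit_log: tuple = ()
    irreducible_nodes: tuple[str, ...] = ()

    def __post_init__(self):
        for n in self.network.nodes:
            if n not in self.rules:
                raise ModelError(f"node {n!r} has no rule")
        for n, r in self.rules.items():
            if n not in self.network.node_set:
                raise ModelError(f"rule for unknown node {n!r}")
            if r.target != n:
                raise ModelError(f"rule target mismatch for {n!r}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.network.nodes))

    def max_level(self, node: str) -> int:
        return self.max_levels.get(node, 1)

    def with_rule(self, rule: Rule, max_level: int | None = None) -> "LogicalModel":
        rules = dict(self.rules)
        rules[rule.target] = rule
        levels = dict(self.max_levels)
        if max_level is not None:
            levels[rule.target] = max_level
        return replace(self, rules=rules, max_levels=levels)

    def clamped(self, clamps: dict) -> "LogicalModel":
        """Rewrite clamped nodes to constant rules (drug targets held at a level)."""
        m = self
        for node, level in (clamps or {}).items():
            if node not in self.network.node_set:
                raise ModelError(f"clamp on unknown node {node!r}")
            m = m.with_rule(ConstantRule(node, int(level)))
        return m


def default_rules(net: RegulatoryNetwork, link_overrides=None,
                  output_rule_mode="net", output_max_level=3) -> LogicalModel:
    """Generic model from a signed network using the standard conventions."""
    overrides = dict(link_overrides or {})
    for n in overrides:
        if n not in net.node_set:
            raise ModelError(f"link-operator override for unknown node {n!r}")
    outputs = set(net.output_nodes or ())
    rules: dict[str, Rule] = {}
    levels: dict[str, int] = {}
    for node in net.nodes:
        acts = net.regulators(node, +1)
        inhs = net.regulators(node, -1)
        if node in outputs:
            rules[node] = CountingRule(
                node,
                positives=tuple(Var(a) for a in acts),
                negatives=tuple(Var(i) for i in inhs),
                max_level=output_max_level,
                count_mode="positive" if output_rule_mode == "positive" else "net",
            )
            levels[node] = output_max_level
        elif not acts and not inhs:
            rules[node] = IdentityRule(node)
            levels[node] = 1
        else:
            rules[node] = LinkRule(node, acts, inhs, overrides.get(node, AND_NOT))
            levels[node] = 1
    return LogicalModel(network=net, rules=rules, max_levels=levels)


# ---------------------------------------------------------------------------
# dynamics


def evaluate(model: LogicalModel, state: State) -> State:
    """Synchronous image: every node's next level from its rule."""
    for n in model.network.nodes:
        if n not in state:
            raise ModelError(f"state missing node {n!r}")
    return {n: model.rules[n].next_value(state) for n in model.nodes}


def _dependency_graph(model: LogicalModel) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(model.network.nodes)
    for n, rule in model.rules.items():
        for r in rule.regulators:
            g.add_edge(r, n)
    return g


def _feedback_nodes(model: LogicalModel) -> tuple[list[str], list[str]]:
    """Greedy feedback vertex set; returns (enumerated nodes, topo order of rest)."""
    g = _dependency_graph(model)
    fvs: list[str] = []
    while True:
        cyclic: set[str] = set()
        for scc in nx.strongly_connected_components(g):
            if len(scc) > 1:
                cyclic |= scc
            else:
                (n,) = scc
                if g.has_edge(n, n):
                    cyclic.add(n)
        if not cyclic:
            break
        pick = max(sorted(cyclic), key=lambda n: (g.in_degree(n) + g.out_degree(n), ))
        fvs.append(pick)
        g.remove_node(pick)
    order = list(nx.topological_sort(g))
    return sorted(fvs), order


def stable_states(model: LogicalModel, clamps=None, enumeration_cap=2_000_000) -> list[State]:
    """All fixed points, in lexicographic order of the sorted-node value tuple.

    Exact and complete: enumerates a feedback vertex set and propagates
    over the remaining acyclic part, keeping self-consistent assignments.
    """
    work = model.clamped(clamps) if clamps else model
    free, order = _feedback_nodes(work)
    ranges = [range(work.max_level(n) + 1) for n in free]
    n_combos = 1
    for r in ranges:
        n_combos *= len(r)
        if n_combos > enumeration_cap:
            raise ModelError(f"fixed-point enumeration exceeds cap ({enumeration_cap})")
    rules = work.rules
    found: list[State] = []
    for combo in itertools.product(*ranges):
        state = dict(zip(free, combo))
        for n in order:
            state[n] = rules[n].next_value(state)
        if all(rules[f].next_value(state) == state[f] for f in free):
            found.append(state)
    names = sorted(work.network.nodes)
    found.sort(key=lambda s: tuple(s[n] for n in names))
    return [{n: s[n] for n in names} for s in found]


@dataclass(frozen=True)
class Attractor:
    kind: str  # "stable_state" | "complex"
    states: tuple  # tuple of State dicts, sorted


@dataclass(frozen=True)
class AttractorAnalysis:
    attractors: tuple[Attractor, ...]
    undecided: bool = False
    n_states_explored: int = 0


def async_attractors(model: LogicalModel, clamps=None, max_states=2 ** 14) -> AttractorAnalysis:
    """Terminal SCCs of the asynchronous (unitary-step) transition graph.

    A state space larger than ``max_states`` yields an explicit undecided
    result rather than a truncated answer.
    """
    work = model.clamped(clamps) if clamps else model
    names = sorted(work.network.nodes)
    clamp_map = dict(clamps or {})
    level_ranges = [
        (range(clamp_map[n], clamp_map[n] + 1) if n in clamp_map
         else range(work.max_level(n) + 1))
        for n in names
    ]
    total = 1
    for r in level_ranges:
        total *= len(r)
    if total > max_states:
        return AttractorAnalysis(attractors=(), undecided=True, n_states_explored=0)
    rules = [work.rules[n] for n in names]
    idx = {n: i for i, n in enumerate(names)}

    g = nx.DiGraph()
    for combo in itertools.product(*level_ranges):
        state = dict(zip(names, combo))
        g.add_node(combo)
        for i, n in enumerate(names):
            target = rules[i].next_value(state)
            cur = combo[i]
            if target != cur:
                step = cur + (1 if target > cur else -1)
                succ = combo[:i] + (step,) + combo[i + 1:]
                g.add_edge(combo, succ)
    cond = nx.condensation(g)
    attractors = []
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            members = sorted(cond.nodes[comp_id]["members"])
            states = tuple(dict(zip(names, m)) for m in members)
            kind = "stable_state" if len(states) == 1 else "complex"
            attractors.append(Attractor(kind=kind, states=states))
    attractors.sort(key=lambda a: tuple(a.states[0][n] for n in names))
    return AttractorAnalysis(attractors=tuple(attractors), undecided=False,
                             n_states_explored=total)


# ---------------------------------------------------------------------------
# reduction


def reduce_model(model: LogicalModel, retain_set) -> LogicalModel:
    """Eliminate nodes outside ``retain_set`` by substituting their rules downstream.

    Only non-self-regulated Boolean nodes are eliminated (substituting a
    variable by a function that does not involve it preserves the fixed
    points of the equation system exactly, so projections onto the
    retained nodes are unchanged).  Elimination may make a remaining node
    self-regulated; such nodes, and multi-valued nodes, are kept and
    reported via ``irreducible_nodes``.
    """
    retain = set(retain_set)
    unknown = retain - set(model.network.nodes)
    if unknown:
        raise ModelError(f"retain_set contains unknown nodes: {sorted(unknown)}")
    rules = dict(model.rules)
    remaining = set(model.network.nodes)
    progress = True
    while progress:
        progress = False
        for node in sorted(remaining - retain):
            rule = rules[node]
            if isinstance(rule, (CountingRule, IdentityRule)):
                continue  # multi-valued or explicit self-loop: keep
            if node in rule.regulators:
                continue  # self-regulated: irreducible
            expression = rule.expr()
            for other in sorted(remaining):
                if other == node:
                    continue
                rules[other] = rules[other].substitute(node, expression)
            del rules[node]
            remaining.discard(node)
            progress = True
    irreducible = tuple(sorted(remaining - retain))
    # rebuild the signed network from rule polarities
    edges = []
    for node in sorted(remaining):
        rule = rules[node]
        if isinstance(rule, CountingRule):
            for e in rule.positives:
                for v, signs in e.polarities().items():
                    for s in signs:
                        edges.append((v, s, node))
            for e in rule.negatives:
                for v, signs in e.polarities().items():
                    for s in signs:
                        edges.append((v, -s, node))
        elif isinstance(rule, IdentityRule):
            edges.append((node, 1, node))
        elif isinstance(rule, ConstantRule):
            pass
        else:
            for v, signs in rule.expr().polarities().items():
                for s in signs:
                    edges.append((v, s, node))
    outputs = model.network.output_nodes
    if outputs is not None and not all(o in remaining for o in outputs):
        outputs = None
    net = make_network(
        edges,
        output_nodes=outputs,
        drug_target_nodes=frozenset(model.network.drug_target_nodes) & remaining,
        extra_nodes=sorted(remaining),
    )
    levels = {n: model.max_level(n) for n in remaining}
    return LogicalModel(network=net, rules=rules, max_levels=levels,
                        edit_log=model.edit_log, irreducible_nodes=irreducible)


def project_states(states, nodes) -> list[State]:
    """Project states onto a node subset, deduplicated and sorted."""
    nodes = sorted(nodes)
    seen = sorted({tuple(s[n] for n in nodes) for s in states})
    return [dict(zip(nodes, t)) for t in seen]


# ---------------------------------------------------------------------------
# edits


@dataclass(frozen=True)
class ModelEdit:
    """One model modification; ``kind`` selects the payload interpretation."""

    kind: str
    payload: tuple  # sorted (key, value) pairs for hashability

    KINDS = ("add_node", "remove_edge", "add_edge", "set_rule",
             "set_max_level", "set_link_operator")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ModelError(f"unknown edit kind {self.kind!r}")

    @property
    def args(self) -> dict:
        return dict(self.payload)

    @classmethod
    def make(cls, kind: str, **kwargs) -> "ModelEdit":
        return cls(kind=kind, payload=tuple(sorted(kwargs.items())))

    @classmethod
    def set_rule(cls, node, expression, max_level=None):
        return cls.make("set_rule", node=node, expression=expression, max_level=max_level)

    @classmethod
    def set_link_operator(cls, node, operator):
        return cls.make("set_link_operator", node=node, operator=operator)

    @classmethod
    def remove_edge(cls, source, target):
        return cls.make("remove_edge", source=source, target=target)

    @classmethod
    def add_edge(cls, source, sign, target):
        return cls.make("add_edge", source=source, sign=sign, target=target)

    @classmethod
    def add_node(cls, node, expression=None, max_level=1):
        return cls.make("add_node", node=node, expression=expression, max_level=max_level)

    @classmethod
    def set_max_level(cls, node, max_level):
        return cls.make("set_max_level", node=node, max_level=max_level)


def apply_edits(model: LogicalModel, edits) -> LogicalModel:
    """Apply edits in order; errors name the offending edit index."""
    m = model
    for i, edit in enumerate(edits):
        try:
            m = _apply_one(m, edit)
        except (ModelError, ExprError, KeyError) as exc:
            raise ModelError(f"edit {i} ({edit.kind}): {exc}") from exc
    return replace(m, edit_log=m.edit_log + tuple(edits))


def _edges_from_expr(node: str, expression: Expr):
    edges = []
    for v, signs in expression.polarities().items():
        for s in signs:
            edges.append((v, s, node))
    return edges


def _apply_one(model: LogicalModel, edit: ModelEdit) -> LogicalModel:
    a = edit.args
    net = model.network
    if edit.kind == "add_node":
        node = a["node"]
        if node in net.node_set:
            raise ModelError(f"node {node!r} already present")
        if a.get("expression"):
            expression = parse_expr(a["expression"])
            missing = expression.variables() - net.node_set - {node}
            if missing:
                raise ModelError(f"rule references unknown nodes {sorted(missing)}")
            rule: Rule = ExprRule(node, expression)
            new_edges = tuple(net.edges) + tuple(_edges_from_expr(node, expression))
        else:
            rule = IdentityRule(node)
            new_edges = net.edges
        new_net = make_network(new_edges, output_nodes=net.output_nodes,
                               drug_target_nodes=net.drug_target_nodes,
                               extra_nodes=tuple(net.nodes) + (node,))
        rules = dict(model.rules)
        rules[node] = rule
        levels = dict(model.max_levels)
        levels[node] = int(a.get("max_level") or 1)
        return replace(model, network=new_net, rules=rules, max_levels=levels)

    if edit.kind == "remove_edge":
        src, tgt = a["source"], a["target"]
        kept = tuple(e for e in net.edges if not (e[0] == src and e[2] == tgt))
        if len(kept) == len(net.edges):
            raise ModelError(f"no edge {src!r} -> {tgt!r}")
        rule = model.rules[tgt]
        if isinstance(rule, LinkRule):
            acts = tuple(x for x in rule.activators if x != src)
            inhs = tuple(x for x in rule.inhibitors if x != src)
            new_rule: Rule = (LinkRule(tgt, acts, inhs, rule.operator)
                              if (acts or inhs) else IdentityRule(tgt))
        elif isinstance(rule, CountingRule):
            new_rule = replace(
                rule,
                positives=tuple(e for e in rule.positives if e.variables() != {src}),
                negatives=tuple(e for e in rule.negatives if e.variables() != {src}),
            )
        elif isinstance(rule, ExprRule):
            new_rule = ExprRule(tgt, rule.expression.substitute({src: Const(False)}))
        else:
            new_rule = rule
        new_net = make_network(kept, output_nodes=net.output_nodes,
                               drug_target_nodes=net.drug_target_nodes,
                               extra_nodes=net.nodes)
        return replace(model, network=new_net).with_rule(new_rule)

    if edit.kind == "add_edge":
        src, sign, tgt = a["source"], int(a["sign"]), a["target"]
        for n in (src, tgt):
            if n not in net.node_set:
                raise ModelError(f"unknown node {n!r}")
        new_net = make_network(tuple(net.edges) + ((src, sign, tgt),),
                               output_nodes=net.output_nodes,
                               drug_target_nodes=net.drug_target_nodes,
                               extra_nodes=net.nodes)
        rule = model.rules[tgt]
        if isinstance(rule, LinkRule):
            acts = rule.activators + ((src,) if sign == 1 else ())
            inhs = rule.inhibitors + ((src,) if sign == -1 else ())
            new_rule: Rule = LinkRule(tgt, acts, inhs, rule.operator)
        elif isinstance(rule, CountingRule):
            if sign == 1:
                new_rule = replace(rule, positives=rule.positives + (Var(src),))
            else:
                new_rule = replace(rule, negatives=rule.negatives + (Var(src),))
        elif isinstance(rule, IdentityRule):
            new_rule = LinkRule(tgt, (src,) if sign == 1 else (), (src,) if sign == -1 else ())
        else:
            raise ModelError(f"{tgt!r} has a free-expression rule; use set_rule")
        return replace(model, network=new_net).with_rule(new_rule)

    if edit.kind == "set_rule":
        node = a["node"]
        if node not in net.node_set:
            raise ModelError(f"unknown node {node!r}")
        expression = parse_expr(a["expression"])
        missing = expression.variables() - net.node_set
        if missing:
            raise ModelError(f"rule references unknown nodes {sorted(missing)}")
        # resync the node's incoming edges with the new rule's polarities
        kept = tuple(e for e in net.edges if e[2] != node)
        new_net = make_network(kept + tuple(_edges_from_expr(node, expression)),
                               output_nodes=net.output_nodes,
                               drug_target_nodes=net.drug_target_nodes,
                               extra_nodes=net.nodes)
        level = a.get("max_level")
        m = replace(model, network=new_net)
        return m.with_rule(ExprRule(node, expression),
                           max_level=int(level) if level is not None else None)

    if edit.kind == "set_max_level":
        node = a["node"]
        if node not in net.node_set:
            raise ModelError(f"unknown node {node!r}")
        levels = dict(model.max_levels)
        levels[node] = int(a["max_level"])
        return replace(model, max_levels=levels)

    if edit.kind == "set_link_operator":
        node = a["node"]
        rule = model.rules.get(node)
        if rule is None:
            raise ModelError(f"unknown node {node!r}")
        if not isinstance(rule, LinkRule):
            raise ModelError(f"{node!r} does not carry a link-operator rule")
        return model.with_rule(LinkRule(node, rule.activators, rule.inhibitors, a["operator"]))

    raise ModelError(f"unknown edit kind {edit.kind!r}")  # pragma: no cover


def edits_to_yaml(edits, path=None) -> str:
    """Serialise an edit list as YAML (inverse of :func:`edits_from_yaml`)."""
    import yaml

    data = [{"kind": e.kind, **{k: v for k, v in e.args.items() if v is not None}}
            for e in edits]
    text = yaml.safe_dump(data, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def edits_from_yaml(source) -> list[ModelEdit]:
    """Load an edit list from YAML/JSON: a sequence of {kind: ..., ...} maps."""
    import yaml

    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = yaml.safe_load(source)
    edits = []
    for item in data or []:
        kind = item.pop("kind")
        edits.append(ModelEdit.make(kind, **item))
    return edits


# ---------------------------------------------------------------------------
# serialization


def write_rules(model: LogicalModel, path=None) -> str:
    """Plain-text rule file: ``node<TAB>expression<TAB>max_level`` lines.

    Counting rules are written as ``@count(pos...; neg...; max=K)``.
    """
    lines = []
    for node in model.nodes:
        rule = model.rules[node]
        if isinstance(rule, CountingRule):
            pos = ",".join(str(e) for e in rule.positives)
            neg = ",".join(str(e) for e in rule.negatives)
            body = f"@count({pos}; {neg}; max={rule.max_level})"
        elif isinstance(rule, ConstantRule):
            body = str(rule.value)
        else:
            body = str(rule.expr())
        lines.append(f"{node}\t{body}\t{model.max_level(node)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_rules(source, network: RegulatoryNetwork | None = None) -> LogicalModel:
    """Parse a rule file written by :func:`write_rules`."""
    from .network import _read_text

    text = _read_text(source)
    rules: dict[str, Rule] = {}
    levels: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 3:
            raise ModelError(f"line {lineno}: expected 3 tab-separated columns")
        node, body, level = cols[0].strip(), cols[1].strip(), int(cols[2])
        levels[node] = level
        if body.startswith("@count(") and body.endswith(")"):
            inner = body[len("@count("):-1]
            pos_s, neg_s, max_s = (p.strip() for p in inner.split(";"))
            positives = tuple(parse_expr(p) for p in pos_s.split(",") if p.strip())
            negatives = tuple(parse_expr(p) for p in neg_s.split(",") if p.strip())
            rules[node] = CountingRule(node, positives, negatives,
                                       max_level=int(max_s.split("=")[1]))
        elif body in ("0", "1") and level == 1:
            rules[node] = ConstantRule(node, int(body))
        elif body == node:
            rules[node] = IdentityRule(node)
        else:
            rules[node] = ExprRule(node, parse_expr(body))
    edges = []
    for node, rule in rules.items():
        if isinstance(rule, CountingRule):
            for e in rule.positives:
                for v, signs in e.polarities().items():
                    edges.extend((v, s, node) for s in signs)
            for e in rule.negatives:
                for v, signs in e.polarities().items():
                    edges.extend((v, -s, node) for s in signs)
        elif isinstance(rule, IdentityRule):
            edges.append((node, 1, node))
        elif isinstance(rule, ExprRule):
            for v, signs in rule.expression.polarities().items():
                edges.extend((v, s, node) for s in signs)
    if network is None:
        network = make_network(edges, extra_nodes=sorted(rules))
    return LogicalModel(network=network, rules=rules, max_levels=levels)
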