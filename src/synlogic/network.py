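"""Signed directed prior-knowledge networks and tabular inputs.

A regulatory network is a signed digraph over named signaling entities.
Node naming follows the convention used in curated cancer-signaling
networks: a bare gene symbol for a single protein, ``SYMBOL_f`` for a
protein family, ``SYMBOL_g`` for a gene, ``SYMBOL_c`` for a complex.
Two designated output nodes (a prosurvival and an antisurvival phenotype
node) summarise the downstream effect of signaling, and a subset of nodes
is marked as druggable targets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx


class NetworkParseError(ValueError):
    pass


class NetworkValidationError(ValueError):
    pass


#: sign vocabularies accepted by default
DEFAULT_SIGN_TOKENS = {
    "activate": 1, "activates": 1, "->": 1, "1": 1, "+": 1, "+1": 1,
    "inhibit": -1, "inhibits": -1, "-|": -1, "-1": -1, "-": -1,
}


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Signed directed interaction network.

    Edges are (source, sign, target) triples with sign in {+1, -1}.
    ``output_nodes`` is the ordered (prosurvival, antisurvival) pair.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, int, str], ...]
    output_nodes: tuple[str, str] | None = None
    drug_target_nodes: frozenset[str] = frozenset()

    def __post_init__(self):
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise NetworkValidationError("duplicate node identifiers")
        for n in self.nodes:
            if not n or n != n.strip():
                raise NetworkValidationError(f"bad node identifier {n!r}")
        for s, sign, t in self.edges:
            if sign not in (1, -1):
                raise NetworkValidationError(f"bad sign {sign!r} on edge {s}->{t}")
            if s not in node_set or t not in node_set:
                raise NetworkValidationError(f"edge endpoint not declared: ({s}, {sign}, {t})")
        if len(set(self.edges)) != len(self.edges):
            raise NetworkValidationError("duplicate edges")
        if self.output_nodes is not None:
            for n in self.output_nodes:
                if n not in node_set:
                    raise NetworkValidationError(f"output node {n!r} not in network")
        for n in self.drug_target_nodes:
            if n not in node_set:
                raise NetworkValidationError(f"drug target node {n!r} not in network")

    # -- convenience accessors -------------------------------------------------
    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)

    def regulators(self, node: str, sign: int | None = None) -> tuple[str, ...]:
        """Sources of incoming edges, optionally restricted to one sign."""
        srcs = [s for s, sg, t in self.edges if t == node and (sign is None or sg == sign)]
        return tuple(sorted(set(srcs)))

    def targets_of(self, node: str) -> tuple[str, ...]:
        return tuple(sorted({t for s, _, t in self.edges if s == node}))

    def to_networkx(self, multigraph: bool = False) -> nx.DiGraph:
        """Export as a (Multi)DiGraph with a ``sign`` edge attribute."""
        g = nx.MultiDiGraph() if multigraph else nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, sign, t in self.edges:
            g.add_edge(s, t, sign=sign)
        return g

    def canonical(self) -> "RegulatoryNetwork":
        return replace(self, nodes=tuple(sorted(self.nodes)), edges=tuple(sorted(self.edges)))


def make_network(edges, output_nodes=None, drug_target_nodes=(), extra_nodes=()):
    """Build a network from an edge iterable, declaring nodes from endpoints."""
    edges = tuple(dict.fromkeys((s, int(sign), t) for s, sign, t in edges))
    nodes: dict[str, None] = {}
    for n in extra_nodes:
        nodes.setdefault(n)
    for s, _, t in edges:
        nodes.setdefault(s)
        nodes.setdefault(t)
    if output_nodes is not None:
        for n in output_nodes:
            nodes.setdefault(n)
    return RegulatoryNetwork(
        nodes=tuple(nodes),
        edges=edges,
        output_nodes=tuple(output_nodes) if output_nodes is not None else None,
        drug_target_nodes=frozenset(drug_target_nodes),
    )


def parse_network(source, sign_tokens=None, delimiter="\t", header_keyword="source",
                  output_nodes=None, drug_target_nodes=(), extra_nodes=()):
    """Parse a 3-column (source, sign, target) interaction table.

    ``source`` may be a path, a file-like object, or the text itself.
    The sign vocabulary is configurable; unknown tokens are rejected with
    the offending line number.  A header row is auto-detected when the
    first row contains ``header_keyword`` (case-insensitive).
    """
    tokens = dict(DEFAULT_SIGN_TOKENS if sign_tokens is None else sign_tokens)
    text = _read_text(source)
    edges: list[tuple[str, int, str]] = []
    lines = text.splitlines()
    start = 0
    if lines:
        first = [c.strip() for c in lines[0].split(delimiter)]
        if any(header_keyword.lower() == c.lower() for c in first):
            start = 1
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cols = [c.strip() for c in raw.split(delimiter)]
        if len(cols) != 3:
            raise NetworkParseError(f"line {lineno}: expected 3 columns, got {len(cols)}")
        src, sign_tok, tgt = cols
        if sign_tok not in tokens:
            raise NetworkParseError(f"line {lineno}: unknown sign token {sign_tok!r}")
        if not src or not tgt:
            raise NetworkParseError(f"line {lineno}: empty node identifier")
        edges.append((src, tokens[sign_tok], tgt))
    return make_network(edges, output_nodes=output_nodes,
                        drug_target_nodes=drug_target_nodes, extra_nodes=extra_nodes)


def write_network(net: RegulatoryNetwork, path=None, delimiter="\t",
                  sign_out=(("1", "-1"))) -> str:
    """Serialise as 3-column text (sorted edges); returns the text."""
    pos_tok, neg_tok = sign_out
    lines = [f"{s}{delimiter}{pos_tok if sign == 1 else neg_tok}{delimiter}{t}"
             for s, sign, t in sorted(net.edges)]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def _read_text(source) -> str:
    if isinstance(source, io.IOBase):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if not source or "\n" in source or "\t" in source:
            return source
        p = Path(source)
        if p.is_file():
            return p.read_text()
        return source
    raise TypeError(f"cannot read network from {type(source)!r}")


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationReport:
    """Report-only summary of structural issues."""

    unreachable_from_targets: tuple[str, ...]
    no_path_to_output: tuple[str, ...]
    self_loops: tuple[str, ...]
    dual_regulations: tuple[tuple[str, str], ...]
    disconnected_outputs: tuple[str, ...]
    isolated_nodes: tuple[str, ...]

    @property
    def connectivity_clean(self) -> bool:
        return not (self.unreachable_from_targets or self.no_path_to_output
                    or self.disconnected_outputs)


def validate_network(net: RegulatoryNetwork) -> ValidationReport:
    g = net.to_networkx()
    outputs = set(net.output_nodes or ())
    targets = set(net.drug_target_nodes)

    reachable_from_targets: set[str] = set()
    for t in targets:
        reachable_from_targets |= {t} | nx.descendants(g, t)
    unreachable = sorted(set(net.nodes) - reachable_from_targets - outputs) if targets else ()

    reaches_output: set[str] = set()
    for o in outputs:
        reaches_output |= {o} | nx.ancestors(g, o)
    no_path = sorted(set(net.nodes) - reaches_output - outputs) if outputs else ()

    self_loops = sorted({s for s, _, t in net.edges if s == t})
    pairs: dict[tuple[str, str], set[int]] = {}
    for s, sign, t in net.edges:
        pairs.setdefault((s, t), set()).add(sign)
    dual = tuple(sorted(k for k, v in pairs.items() if len(v) == 2))
    disconnected_outputs = tuple(sorted(o for o in outputs if g.in_degree(o) == 0))
    isolated = tuple(sorted(n for n in net.nodes if g.degree(n) == 0))
    return ValidationReport(
        unreachable_from_targets=tuple(unreachable),
        no_path_to_output=tuple(no_path),
        self_loops=tuple(self_loops),
        dual_regulations=dual,
        disconnected_outputs=disconnected_outputs,
        isolated_nodes=isolated,
    )


# ---------------------------------------------------------------------------
# drug panel


@dataclass(frozen=True)
class DrugPanel:
    """Mapping from drug abbreviation to its target node(s)."""

    entries: dict[str, frozenset[str]]
    full_names: dict[str, str] = field(default_factory=dict)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    def targets(self, drugs) -> frozenset[str]:
        """Union of target nodes over one or several drugs."""
        if isinstance(drugs, str):
            drugs = (drugs,)
        out: set[str] = set()
        for d in drugs:
            out |= self.entries[d]
        return frozenset(out)

    def pairs(self) -> tuple[tuple[str, str], ...]:
        ds = self.drugs
        return tuple((a, b) for i, a in enumerate(ds) for b in ds[i + 1:])


def make_panel(entries, network: RegulatoryNetwork | None = None, full_names=None) -> DrugPanel:
    mapped = {d: frozenset(t if not isinstance(t, str) else (t,)) for d, t in dict(entries).items()}
    if network is not None:
        for d, ts in mapped.items():
            for t in ts:
                if t not in network.node_set:
                    raise NetworkValidationError(f"drug {d!r} targets unknown node {t!r}")
    return DrugPanel(entries=mapped, full_names=dict(full_names or {}))


def parse_panel(source, network: RegulatoryNetwork | None = None, delimiter="\t") -> DrugPanel:
    """Parse a panel table: abbreviation, comma-separated targets[, full name]."""
    text = _read_text(source)
    entries: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    lines = text.splitlines()
    start = 0
    if lines and "target" in lines[0].lower():
        start = 1
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cols = [c.strip() for c in raw.split(delimiter)]
        if len(cols) < 2:
            raise NetworkParseError(f"line {lineno}: expected >=2 columns")
        abbr = cols[0]
        targets = frozenset(t.strip() for t in cols[1].split(",") if t.strip())
        if not targets:
            raise NetworkParseError(f"line {lineno}: drug {abbr!r} has no targets")
        entries[abbr] = targets
        if len(cols) >= 3 and cols[2]:
            names[abbr] = cols[2]
    return make_panel(entries, network=network, full_names=names)


def write_panel(panel: DrugPanel, path=None, delimiter="\t") -> str:
    lines = []
    for d in panel.drugs:
        row = [d, ",".join(sorted(panel.entries[d]))]
        if d in panel.full_names:
            row.append(panel.full_names[d])
        lines.append(delimiter.join(row))
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text
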