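"""High-influence node identification, restricted calibration, mechanism subgraphs.

A node is probed by clamping it at its wild-type stable-state value
("fix") and at the inverted value ("invert"), re-running every single-
and double-drug simulation, and recording which synergy calls change
relative to the unperturbed (wild-type) model.  Nodes changing at least
one call, or inducing a complex/undecided attractor in any condition,
are classed high-influence; the rest are low-influence.  Ranking is by
the total number of changed calls, ties broken by node identifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .calibration import ActivityProfile, CalibrationResult, calibrate, restrict_profile
from .model import LogicalModel, ModelError, State, stable_states
from .network import DrugPanel
from .perturb import SynergyCallSet, predict_synergies, simulate
from .screening import ConfusionSummary, ObservedCallSet, confusion

FIX = "fix"
INVERT = "invert"


@dataclass(frozen=True)
class InfluenceRecord:
    node: str
    mode: str  # fix | invert
    gains: dict  # class label -> count (classes gained vs wild type)
    losses: dict  # class label -> count
    changed_pairs: dict  # pair -> (wild-type call, mutant call)
    complex_attractor_count: int

    @property
    def total_changes(self) -> int:
        return len(self.changed_pairs)


@dataclass(frozen=True)
class InfluenceClassification:
    high_influence: frozenset
    low_influence: frozenset
    ranking: tuple[str, ...]  # most influential first
    totals: dict  # node -> total changes (fix + invert)


def _call_class(call: bool | None, observed_call: bool | None) -> str:
    if call is None or observed_call is None:
        return "NA"
    if call:
        return "TP" if observed_call else "FP"
    return "FN" if observed_call else "TN"


def _condition_kinds(calls: SynergyCallSet) -> list[str]:
    kinds = [r.attractor_kind for r in calls.singles.values()]
    # pair attractor kinds are implicit in NA viabilities; count undecided pairs
    kinds += ["undecided" for c in calls.pairs.values()
              if c.viability_ab is None]
    return kinds


def influence_sweep(model: LogicalModel, panel: DrugPanel,
                    reference_state: State | None = None,
                    profile: ActivityProfile | None = None,
                    observed: ObservedCallSet | None = None,
                    nodes=None, max_states: int = 2 ** 12) -> list[InfluenceRecord]:
    """Fix/invert every Boolean non-output node and re-predict all conditions.

    The wild-type stable state supplies each node's reference value; it is
    selected by ``profile`` agreement when given, else lexicographically.
    With ``observed`` the changed calls are classified into TP/TN/FP/FN
    gains and losses; without it the classes are "synergy"/"no_synergy".
    """
    if reference_state is None:
        states = stable_states(model)
        if not states:
            raise ModelError("model has no wild-type stable state")
        if profile is not None:
            from .calibration import select_state
            reference_state, _ = select_state(states, profile)
        else:
            reference_state = states[0]
    wt = predict_synergies(model, panel, reference_state=reference_state,
                           max_states=max_states)
    outputs = set(model.network.output_nodes or ())
    if nodes is None:
        nodes = [n for n in sorted(model.network.nodes)
                 if n not in outputs and model.max_level(n) == 1]
    obs_calls = observed.calls if observed is not None else {}
    records = []
    for node in nodes:
        wt_value = int(reference_state[node] >= 1)
        for mode, value in ((FIX, wt_value), (INVERT, 1 - wt_value)):
            mut = predict_synergies(model, panel, reference_state=reference_state,
                                    extra_clamps={node: value}, max_states=max_states)
            gains: dict = {}
            losses: dict = {}
            changed: dict = {}
            for pair, call in mut.pairs.items():
                old = wt.pairs[pair].predicted
                new = call.predicted
                if old == new:
                    continue
                changed[pair] = (old, new)
                y = obs_calls.get(pair) if observed is not None else None
                if observed is not None:
                    old_cls, new_cls = _call_class(old, y), _call_class(new, y)
                else:
                    cls = lambda c: ("NA" if c is None
                                     else ("synergy" if c else "no_synergy"))
                    old_cls, new_cls = cls(old), cls(new)
                gains[new_cls] = gains.get(new_cls, 0) + 1
                losses[old_cls] = losses.get(old_cls, 0) + 1
            n_complex = sum(1 for k in _condition_kinds(mut)
                            if k in ("complex", "undecided"))
            records.append(InfluenceRecord(node=node, mode=mode, gains=gains,
                                           losses=losses, changed_pairs=changed,
                                           complex_attractor_count=n_complex))
    return records


def classify_and_rank(records) -> InfluenceClassification:
    totals: dict[str, int] = {}
    complexes: dict[str, int] = {}
    for r in records:
        totals[r.node] = totals.get(r.node, 0) + r.total_changes
        complexes[r.node] = complexes.get(r.node, 0) + r.complex_attractor_count
    high = frozenset(n for n in totals if totals[n] > 0 or complexes[n] > 0)
    low = frozenset(totals) - high
    ranking = tuple(sorted(totals, key=lambda n: (-totals[n], n)))
    return InfluenceClassification(high_influence=high, low_influence=low,
                                   ranking=ranking, totals=totals)


def records_to_frame(records):
    """Influence records as a tidy DataFrame (one row per node x mode)."""
    import pandas as pd

    classes = sorted({c for r in records for c in (*r.gains, *r.losses)})
    rows = []
    for r in records:
        row = {"node": r.node, "mode": r.mode,
               "complex_attractors": r.complex_attractor_count,
               "total_changes": r.total_changes}
        for c in classes:
            row[f"gain_{c}"] = r.gains.get(c, 0)
            row[f"loss_{c}"] = r.losses.get(c, 0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# restricted-calibration experiment


@dataclass(frozen=True)
class RestrictedCalibrationOutcome:
    label: str
    calibration: CalibrationResult
    calls: SynergyCallSet
    summary: ConfusionSummary


def restricted_calibration_experiment(model: LogicalModel, profile: ActivityProfile,
                                      classification: InfluenceClassification,
                                      panel: DrugPanel, observed: ObservedCallSet,
                                      k_top: int = 36, k_bottom: int = 38,
                                      max_rounds: int = 10) -> dict:
    """Calibrate to the full profile, the top-k influential and the bottom-k
    non-influential node subsets, and score each against the observed calls."""
    ranking = classification.ranking
    if k_top > len(ranking) or k_bottom > len(ranking):
        raise ModelError(f"k exceeds the {len(ranking)} swept nodes")
    subsets = {
        "full": None,
        "top_influential": set(ranking[:k_top]),
        "bottom_noninfluential": set(ranking[-k_bottom:]),
    }
    out = {}
    for label, subset in subsets.items():
        prof = profile if subset is None else restrict_profile(profile, subset)
        cal = calibrate(model, prof, max_rounds=max_rounds)
        calls = predict_synergies(cal.model, panel,
                                  reference_state=cal.selected_state,
                                  cell_line=profile.cell_line)
        out[label] = RestrictedCalibrationOutcome(
            label=label, calibration=cal, calls=calls,
            summary=confusion(calls.predictions(), observed))
    return out


# ---------------------------------------------------------------------------
# mechanism subgraphs


def mechanism_subgraph(model: LogicalModel, pair, records, panel: DrugPanel,
                       reference_state: State | None = None) -> nx.DiGraph:
    """Build the annotated putative-mechanism subgraph for a predicted synergy.

    Steps: collect the pair-specific influential nodes (excluding any with
    complex-attractor occurrences); induce the subgraph; knock the
    furthest-downstream members in/out under the double perturbation and
    add every node whose stable-state activity changes; prune non-output
    sinks.  Node attribute ``role`` is ``influence_loss``/``influence_gain``
    (per the direction of the call change) or ``activity_altered``.
    """
    pair = tuple(sorted(pair))
    wt_call = simulate_pair_call(model, pair, panel, reference_state)
    if wt_call is not True:
        raise ModelError(f"pair {pair} is not predicted synergistic")

    by_node: dict[str, set[str]] = {}
    excluded = {r.node for r in records if r.complex_attractor_count > 0}
    for r in records:
        if r.node in excluded or pair not in r.changed_pairs:
            continue
        old, new = r.changed_pairs[pair]
        role = "influence_loss" if (old is True and new is not True) else "influence_gain"
        by_node.setdefault(r.node, set()).add(role)
    influential = sorted(by_node)

    g_full = model.network.to_networkx()
    sub_nodes = set(influential)
    sub = g_full.subgraph(sub_nodes).copy()
    downstream = sorted(n for n in sub.nodes if sub.out_degree(n) == 0)

    clamps = {t: 0 for t in panel.targets(pair)}
    base_states = stable_states(model, clamps)
    altered: set[str] = set()
    if base_states:
        from .perturb import _pick_state
        base = _pick_state(base_states, reference_state)
        for node in downstream:
            for forced in (0, 1):
                ko_states = stable_states(model, {**clamps, node: forced})
                if not ko_states:
                    continue
                ko = _pick_state(ko_states, reference_state)
                altered |= {n for n in base if ko[n] != base[n] and n != node}
    sub_nodes |= altered
    sub = g_full.subgraph(sub_nodes).copy()

    outputs = set(model.network.output_nodes or ())
    sinks = [n for n in sub.nodes if sub.out_degree(n) == 0 and n not in outputs]
    sub.remove_nodes_from(sinks)

    for n in sub.nodes:
        if n in by_node:
            roles = by_node[n]
            sub.nodes[n]["role"] = ("influence_loss" if "influence_loss" in roles
                                    else "influence_gain")
        else:
            sub.nodes[n]["role"] = "activity_altered"
    return sub


def simulate_pair_call(model, pair, panel, reference_state):
    a, b = pair
    va = simulate(model, a, panel, reference_state).viability
    vb = simulate(model, b, panel, reference_state).viability
    vab = simulate(model, pair, panel, reference_state).viability
    if None in (va, vb, vab):
        return None
    return vab < min(va, vb)


def subgraph_to_edgelist(sub: nx.DiGraph):
    """Edge-list DataFrame with a node-role table for export."""
    import pandas as pd

    edges = pd.DataFrame(
        [(u, v, d.get("sign", 0)) for u, v, d in sub.edges(data=True)],
        columns=["source", "target", "sign"])
    nodes = pd.DataFrame(
        [(n, sub.nodes[n].get("role", "")) for n in sorted(sub.nodes)],
        columns=["node", "role"])
    return edges, nodes
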