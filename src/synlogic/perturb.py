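"""Drug perturbation simulation and synergy calling.

A drug is simulated by clamping all of its target nodes to 0 (full
inhibition).  Model *Viability* is the prosurvival output level minus the
antisurvival output level, read from the stable state reached under the
perturbation.  When no fixed point exists, the model is reduced (keeping
drug targets, outputs and irreducible loops) and the asynchronous
attractors of the reduced model are analyzed; output levels of a complex
attractor are averaged over its states (configurable to min/max).

A drug pair is called synergistic when the combination viability is
*strictly* below both single-drug viabilities (the model-side analogue of
a highest-single-agent excess).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (Attractor, LogicalModel, ModelError, State,
                    async_attractors, reduce_model, stable_states)
from .network import DrugPanel


def pair_count(n_drugs: int) -> int:
    """Number of unordered drug pairs from a panel of ``n_drugs`` inhibitors."""
    return n_drugs * (n_drugs - 1) // 2


@dataclass(frozen=True)
class PerturbationResult:
    condition: frozenset  # drug abbreviations, |condition| <= 2
    attractor_kind: str  # "stable_state" | "complex" | "undecided"
    prosurvival: float | None
    antisurvival: float | None

    @property
    def viability(self) -> float | None:
        if self.prosurvival is None or self.antisurvival is None:
            return None
        return self.prosurvival - self.antisurvival


@dataclass(frozen=True)
class PairCall:
    drug_a: str
    drug_b: str
    viability_a: float | None
    viability_b: float | None
    viability_ab: float | None
    predicted: bool | None  # None = NA (undecided attractor)


@dataclass(frozen=True)
class SynergyCallSet:
    cell_line: str
    singles: dict  # drug -> PerturbationResult
    pairs: dict  # (a, b) sorted tuple -> PairCall

    def predictions(self) -> dict:
        return {p: c.predicted for p, c in self.pairs.items()}

    @property
    def n_predicted(self) -> int:
        return sum(1 for c in self.pairs.values() if c.predicted)


def _hamming(a: State, b: State) -> int:
    return sum(1 for n in a if n in b and a[n] != b[n])


def _pick_state(states, reference: State | None) -> State:
    names = sorted(states[0])
    if reference is None:
        return states[0]  # stable_states output is lexicographically sorted
    key = lambda s: (_hamming(s, reference), tuple(s[n] for n in names))
    return min(states, key=key)


def _pick_attractor(attractors, reference: State | None) -> Attractor:
    def avg_hamming(att: Attractor) -> float:
        if reference is None:
            return 0.0
        return sum(_hamming(s, reference) for s in att.states) / len(att.states)

    names = sorted(attractors[0].states[0])
    key = lambda a: (avg_hamming(a), tuple(a.states[0][n] for n in names))
    return min(attractors, key=key)


def _output_level(states, node, mode):
    levels = [s[node] for s in states]
    if mode == "min":
        return float(min(levels))
    if mode == "max":
        return float(max(levels))
    return sum(levels) / len(levels)


def simulate(model: LogicalModel, drugs, panel: DrugPanel,
             reference_state: State | None = None, extra_clamps=None,
             max_states: int = 2 ** 14, complex_mode: str = "mean") -> PerturbationResult:
    """Simulate a 0/1/2-drug condition and read out the output-node levels.

    ``reference_state`` (typically the calibrated wild-type stable state)
    disambiguates multistability: among stable states the one closest in
    Hamming distance is taken, ties broken lexicographically.
    ``extra_clamps`` supports the influence sweep's node fixations.
    """
    drugs = frozenset((drugs,) if isinstance(drugs, str) else drugs)
    if len(drugs) > 2:
        raise ModelError("conditions hold at most two drugs")
    outputs = model.network.output_nodes
    if outputs is None:
        raise ModelError("model has no designated output nodes")
    pro, anti = outputs
    clamps = {t: 0 for t in panel.targets(drugs)}
    clamps.update(extra_clamps or {})
    states = stable_states(model, clamps)
    if states:
        chosen = _pick_state(states, reference_state)
        return PerturbationResult(condition=drugs, attractor_kind="stable_state",
                                  prosurvival=float(chosen[pro]),
                                  antisurvival=float(chosen[anti]))
    retain = set(clamps) | set(outputs)
    retain |= {n for n in model.network.nodes if model.max_level(n) > 1}
    clamped = model.clamped(clamps)
    reduced = reduce_model(clamped, retain & set(model.network.nodes))
    analysis = async_attractors(reduced, max_states=max_states)
    if analysis.undecided or not analysis.attractors:
        return PerturbationResult(condition=drugs, attractor_kind="undecided",
                                  prosurvival=None, antisurvival=None)
    ref = None
    if reference_state is not None:
        ref = {n: v for n, v in reference_state.items() if n in reduced.network.node_set}
    att = _pick_attractor(list(analysis.attractors), ref)
    return PerturbationResult(
        condition=drugs,
        attractor_kind=att.kind,
        prosurvival=_output_level(att.states, pro, complex_mode),
        antisurvival=_output_level(att.states, anti, complex_mode),
    )


def predict_synergies(model: LogicalModel, panel: DrugPanel,
                      reference_state: State | None = None, cell_line: str = "",
                      extra_clamps=None, max_states: int = 2 ** 14,
                      complex_mode: str = "mean") -> SynergyCallSet:
    """Call synergy for every unordered pair in the panel.

    ``predicted`` is True iff viability(A+B) < min(viability(A), viability(B))
    with strict inequality; any undecided member viability yields NA.
    """
    if len(panel.drugs) < 2:
        raise ModelError("panel needs at least two drugs")
    kwargs = dict(reference_state=reference_state, extra_clamps=extra_clamps,
                  max_states=max_states, complex_mode=complex_mode)
    singles = {d: simulate(model, d, panel, **kwargs) for d in panel.drugs}
    pairs = {}
    for a, b in panel.pairs():
        res = simulate(model, (a, b), panel, **kwargs)
        va, vb, vab = singles[a].viability, singles[b].viability, res.viability
        if va is None or vb is None or vab is None:
            predicted = None
        else:
            predicted = vab < min(va, vb)
        pairs[(a, b)] = PairCall(drug_a=a, drug_b=b, viability_a=va,
                                 viability_b=vb, viability_ab=vab, predicted=predicted)
    return SynergyCallSet(cell_line=cell_line, singles=singles, pairs=pairs)


def calls_to_frame(calls: SynergyCallSet):
    """Predictions as a DataFrame (cell_line, drugA, drugB, viabilities, predicted)."""
    import pandas as pd

    rows = []
    for (a, b), c in sorted(calls.pairs.items()):
        rows.append({
            "cell_line": calls.cell_line, "drug_a": a, "drug_b": b,
            "viability_a": c.viability_a, "viability_b": c.viability_b,
            "viability_ab": c.viability_ab,
            "predicted": "NA" if c.predicted is None else int(c.predicted),
        })
    return pd.DataFrame(rows)
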