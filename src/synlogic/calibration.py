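"""Baseline activity profiles and cell-line calibration of logical models.

Calibration searches for a minimal set of link-operator flips
(AND NOT -> OR NOT) that brings a stable state of the generic model into
agreement with a 0/1/NA baseline activity profile.  The search is a
strict greedy: candidate flips are proposed in rounds mirroring the
manual procedure used for this class of models -- first should-be-active
nodes whose inhibitors are active, then the inactive negative regulators
of should-be-inactive nodes, then remaining should-be-active mismatches
-- and a flip is kept only if it strictly increases the fraction of
matched profile entries.  Few changes are thereby preferred over many.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .model import (AND_NOT, OR_NOT, IdentityRule, LinkRule, LogicalModel,
                    ModelEdit, State, apply_edits, stable_states)

NA = None


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityProfile:
    """Per-node baseline activity: 0, 1 or NA (None)."""

    cell_line: str
    values: dict  # node -> 0 | 1 | None
    source: str = "literature"

    def __post_init__(self):
        for n, v in self.values.items():
            if v not in (0, 1, None):
                raise CalibrationError(f"{n}: profile value must be 0, 1 or NA, got {v!r}")

    def non_na(self) -> dict:
        return {n: v for n, v in self.values.items() if v is not None}

    @property
    def n_non_na(self) -> int:
        return len(self.non_na())


def combine_profiles(literature: ActivityProfile, omics: ActivityProfile) -> ActivityProfile:
    """Overlay two profiles, literature taking priority over omics."""
    if literature.cell_line != omics.cell_line:
        raise CalibrationError(
            f"cell-line mismatch: {literature.cell_line!r} vs {omics.cell_line!r}")
    nodes = dict.fromkeys(list(literature.values) + list(omics.values))
    values = {}
    for n in nodes:
        lit = literature.values.get(n)
        values[n] = lit if lit is not None else omics.values.get(n)
    return ActivityProfile(cell_line=literature.cell_line, values=values, source="combined")


def restrict_profile(profile: ActivityProfile, node_subset) -> ActivityProfile:
    subset = set(node_subset)
    values = {n: (v if n in subset else None) for n, v in profile.values.items()}
    return ActivityProfile(cell_line=profile.cell_line, values=values, source=profile.source)


def agreement(state: State, profile: ActivityProfile) -> float:
    """Fraction of non-NA profile entries matched by the state (level>=1 ~ active)."""
    entries = profile.non_na()
    entries = {n: v for n, v in entries.items() if n in state}
    if not entries:
        raise CalibrationError("profile has no non-NA entries over the model nodes")
    hits = sum(1 for n, v in entries.items() if int(state[n] >= 1) == v)
    return hits / len(entries)


def select_state(states, profile: ActivityProfile) -> tuple[State, float]:
    """Pick the stable state maximizing profile agreement; ties lexicographic."""
    if not states:
        raise CalibrationError("no stable state to select from")
    names = sorted(states[0])
    scored = [(agreement(s, profile), tuple(s[n] for n in names)) for s in states]
    best_score = max(sc for sc, _ in scored)
    best_tuple = min(t for sc, t in scored if sc == best_score)
    return dict(zip(names, best_tuple)), best_score


@dataclass(frozen=True)
class CalibrationResult:
    model: LogicalModel
    changes: tuple[ModelEdit, ...]
    matched_fraction: float
    selected_state: State
    converged: bool
    log: tuple[str, ...] = ()


def _flip(model: LogicalModel, node: str) -> LogicalModel:
    return apply_edits(model, [ModelEdit.set_link_operator(node, OR_NOT)])


def _flippable(model: LogicalModel, node: str) -> bool:
    rule = model.rules.get(node)
    return (isinstance(rule, LinkRule) and rule.operator == AND_NOT
            and rule.activators and rule.inhibitors)


def _baseline_active(node, profile, state):
    v = profile.values.get(node)
    if v is not None:
        return v == 1
    return state.get(node, 0) >= 1


def calibrate(model: LogicalModel, profile: ActivityProfile,
              max_rounds: int = 10) -> CalibrationResult:
    """Greedy link-operator calibration against a baseline profile."""
    if profile.n_non_na == 0:
        raise CalibrationError("profile is empty")
    log: list[str] = []
    changes: list[ModelEdit] = []
    current = model
    # identity-rule inputs are free in the topology; the baseline pins them
    input_clamps = {n: v for n, v in profile.non_na().items()
                    if isinstance(model.rules.get(n), IdentityRule)}
    if input_clamps:
        log.append(f"pinned {len(input_clamps)} input node(s) to baseline values")
    states = stable_states(current, input_clamps)
    if not states:
        return CalibrationResult(model=current, changes=(), matched_fraction=0.0,
                                 selected_state={}, converged=False,
                                 log=("initial model has no stable state",))
    state, matched = select_state(states, profile)
    log.append(f"initial agreement {matched:.3f}")

    def candidates(phase: int) -> list[str]:
        cands: list[str] = []
        if phase in (1, 3):
            for n, v in sorted(profile.non_na().items()):
                if v == 1 and state.get(n, 0) == 0 and _flippable(current, n):
                    rule = current.rules[n]
                    if phase == 3 or any(_baseline_active(i, profile, state)
                                         for i in rule.inhibitors):
                        cands.append(n)
        else:  # phase 2: activate the inactive inhibitors of should-be-inactive nodes
            for n, v in sorted(profile.non_na().items()):
                if v == 0 and state.get(n, 0) >= 1:
                    rule = current.rules.get(n)
                    if not isinstance(rule, LinkRule):
                        continue
                    for r in rule.inhibitors:
                        if state.get(r, 0) == 0 and _flippable(current, r):
                            cands.append(r)
        return sorted(dict.fromkeys(cands))

    for round_no in range(max_rounds):
        improved_this_round = False
        for phase in (1, 2, 3):
            while matched < 1.0:
                accepted = False
                for node in candidates(phase):
                    trial = _flip(current, node)
                    trial_states = stable_states(trial, input_clamps)
                    if not trial_states:
                        continue
                    t_state, t_matched = select_state(trial_states, profile)
                    if t_matched > matched:
                        current, state, matched = trial, t_state, t_matched
                        changes.append(ModelEdit.set_link_operator(node, OR_NOT))
                        log.append(f"round {round_no + 1} phase {phase}: "
                                   f"flip {node} -> OR_NOT, agreement {matched:.3f}")
                        accepted = improved_this_round = True
                        break
                if not accepted:
                    break
            if matched >= 1.0:
                break
        if matched >= 1.0 or not improved_this_round:
            break
    converged = matched >= 1.0
    if not converged:
        log.append(f"stopped at agreement {matched:.3f} with {len(changes)} change(s)")
    return CalibrationResult(model=current, changes=tuple(changes),
                             matched_fraction=matched, selected_state=state,
                             converged=converged, log=tuple(log))


# ---------------------------------------------------------------------------
# profile IO


def read_profile(source, cell_line="unknown", source_tag="literature",
                 delimiter="\t") -> ActivityProfile:
    """Read a profile TSV: node<TAB>value with NA token ``NA``."""
    from .network import _read_text

    text = _read_text(source)
    values: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cols = [c.strip() for c in raw.split(delimiter)]
        if cols[0].lower() == "node":
            continue
        if len(cols) != 2:
            raise CalibrationError(f"line {lineno}: expected 2 columns")
        node, val = cols
        if val.upper() == "NA":
            values[node] = None
        elif val in ("0", "1"):
            values[node] = int(val)
        else:
            raise CalibrationError(f"line {lineno}: bad value {val!r}")
    return ActivityProfile(cell_line=cell_line, values=values, source=source_tag)


def write_profile(profile: ActivityProfile, path=None, delimiter="\t") -> str:
    lines = [f"{n}{delimiter}{'NA' if v is None else v}"
             for n, v in sorted(profile.values.items())]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text
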