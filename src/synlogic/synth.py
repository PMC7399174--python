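"""Synthetic study systems with planted ground truth.

Everything the pipeline consumes can be generated here: signed random
networks with two phenotype outputs, a "cell line" logical model whose
link-operator flips and stable state are known, literature-like and
omics-like baseline activity profiles derived from that stable state,
a drug panel, and a dose-matrix viability screen with planted
HSA-synergistic pairs.

The bundle's network is built around a convergence motif mirroring how
synergies arise in curated signaling models: two drug-target branches
redundantly sustain a downstream coincidence node (``M = C1 & C2`` with
``C1 = B1 | B2``), so only the *pair* of upstream inhibitions silences
the prosurvival contribution of ``M``.  Single drugs leave viability
untouched, the planted pairs drop it by one level, and the planted
coincidence node is the strongest influence-sweep hit by construction.
All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import ActivityProfile, write_profile
from .model import (OR_NOT, LogicalModel, ModelEdit, apply_edits,
                    default_rules, stable_states)
from .network import (DrugPanel, RegulatoryNetwork, make_network, make_panel,
                      write_network, write_panel)
from .screening import ScreenRecord, write_screen_csv

PRO = "Prosurvival"
ANTI = "Antisurvival"


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# random networks (engine-test workhorse)


def gen_network(n_nodes: int = 20, n_edges: int | None = None,
                frac_inhibitory: float = 0.25, n_targets: int = 4,
                seed: int = 0, n_cycles: int = 0, n_inputs: int = 2) -> RegulatoryNetwork:
    """Random signed digraph with two output nodes wired from a terminal layer.

    Nodes are arranged in a random topological order; every non-input node
    receives at least one edge from an earlier node, each output node gets
    >= 3 regulators from the last third, and ``n_cycles`` back-edges add
    feedback.  Deterministic given ``seed``.
    """
    if n_targets >= n_nodes - 2:
        raise SynthError("n_targets must be < n_nodes - 2")
    n_signal = n_nodes - 2
    if n_signal < max(4, n_inputs + 1):
        raise SynthError("network too small")
    rng = np.random.default_rng(seed)
    signal = [f"N{i:03d}" for i in range(n_signal)]
    edges: set[tuple[str, int, str]] = set()

    def sign() -> int:
        return -1 if rng.random() < frac_inhibitory else 1

    for i in range(n_inputs, n_signal):
        j = int(rng.integers(0, i))
        edges.add((signal[j], sign(), signal[i]))
    tail = signal[max(0, n_signal - max(4, n_signal // 3)):]
    for out in (PRO, ANTI):
        regs = rng.choice(len(tail), size=min(3, len(tail)), replace=False)
        for r in sorted(regs):
            edges.add((tail[r], sign(), out))
    min_edges = len(edges)
    max_extra = n_signal * (n_signal - 1) // 2
    if n_edges is None:
        n_edges = min_edges
    if n_edges < min_edges or n_edges > min_edges + max_extra:
        raise SynthError(f"n_edges={n_edges} infeasible (min {min_edges})")
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        i, j = rng.integers(0, n_signal, size=2)
        if i == j:
            continue
        i, j = (int(min(i, j)), int(max(i, j)))
        cand = (signal[i], sign(), signal[j])
        if (signal[i], -cand[1], signal[j]) in edges:
            continue
        edges.add(cand)
    for _ in range(n_cycles):
        j = int(rng.integers(n_inputs, n_signal))
        i = int(rng.integers(0, j))
        edges.add((signal[j], sign(), signal[i]))
    pool_end = min(n_signal, max(n_inputs + n_targets, n_signal // 2))
    pool = range(n_inputs, pool_end)
    if n_targets > len(pool):
        raise SynthError("n_targets exceeds the available non-input nodes")
    targets = [signal[i] for i in sorted(rng.choice(pool, size=n_targets, replace=False))]
    return make_network(sorted(edges), output_nodes=(PRO, ANTI),
                        drug_target_nodes=targets, extra_nodes=signal)


# ---------------------------------------------------------------------------
# the planted bundle


@dataclass(frozen=True)
class SyntheticBundle:
    network: RegulatoryNetwork
    generic_model: LogicalModel
    planted_model: LogicalModel
    planted_flips: tuple[str, ...]
    truth_state: dict
    profile_truth: ActivityProfile
    profile_literature: ActivityProfile
    profile_omics: ActivityProfile
    panel: DrugPanel
    screen_records: tuple
    planted_synergies: frozenset  # of sorted drug-pair tuples
    bottleneck_node: str
    params: dict
    seed: int


def _motif_network(n_drugs: int, n_filler: int, rng) -> tuple[RegulatoryNetwork, list[str]]:
    if n_drugs < 4:
        raise SynthError("the bundle motif needs at least 4 drugs")
    inputs = ["IN1", "IN2"]
    targets = [f"TGT{i}" for i in range(1, n_drugs + 1)]
    branches = [f"B{i}" for i in range(1, 5)]
    fillers = [f"F{i:02d}" for i in range(1, n_filler + 1)]
    edges: list[tuple[str, int, str]] = []
    for i, t in enumerate(targets):
        edges.append((inputs[i % 2], 1, t))
    for i, b in enumerate(branches):
        edges.append((targets[i], 1, b))
    edges += [("B1", 1, "C1"), ("B2", 1, "C1"), ("B3", 1, "C2"), ("B4", 1, "C2"),
              ("C1", 1, "M"), ("C2", 1, "M"),
              ("IN1", 1, "Z1"), ("IN2", 1, "Z2"),
              ("IN1", -1, "R1"), ("IN2", -1, "R2"), ("IN1", -1, "R3"),
              ("Z1", 1, PRO), ("Z2", 1, PRO), ("M", 1, PRO), ("R1", -1, PRO),
              ("R1", 1, ANTI), ("R2", 1, ANTI), ("R3", 1, ANTI)]
    active_pool = ["IN1", "IN2", "Z1", "Z2"]
    for t in targets[4:]:
        q = f"Q{t[3:]}"
        edges += [(t, 1, q), ("IN1", 1, q), (q, -1, ANTI)]
        active_pool.append(q)
    all_upstream = inputs + targets + branches + ["C1", "C2", "Z1", "Z2"]
    for f in fillers:
        act1 = active_pool[int(rng.integers(0, len(active_pool)))]
        act2 = all_upstream[int(rng.integers(0, len(all_upstream)))]
        inh = active_pool[int(rng.integers(0, len(active_pool)))]
        edges.append((act1, 1, f))
        if act2 not in (act1, inh):
            edges.append((act2, 1, f))
        edges.append((inh, -1, f))
        edges.append((f, -1, ANTI))
    net = make_network(dict.fromkeys(edges), output_nodes=(PRO, ANTI),
                       drug_target_nodes=targets)
    return net, fillers


def make_bundle(seed: int = 0, n_nodes: int = 28, n_drugs: int = 6,
                k_flips: int = 2, flip_fraction: float = 0.0,
                na_fraction: float = 0.0, lit_size: int = 9, n_doses: int = 3,
                excess_depth: float = -0.2, noise_sd: float = 0.0,
                cell_line: str = "SYN-1") -> SyntheticBundle:
    """Generate the full synthetic study: network, models, profiles, screen."""
    rng = np.random.default_rng(seed)
    motif_size = 2 + n_drugs + 4 + 3 + 2 + 3 + max(0, n_drugs - 4) + 2
    n_filler = n_nodes - motif_size
    if n_filler < k_flips:
        raise SynthError(f"n_nodes={n_nodes} leaves {n_filler} filler nodes; "
                         f"need >= k_flips={k_flips}")
    net, fillers = _motif_network(n_drugs, n_filler, rng)

    generic = apply_edits(default_rules(net),
                          [ModelEdit.set_rule("M", "C1 & C2")])
    flip_nodes = tuple(sorted(
        fillers[i] for i in rng.choice(len(fillers), size=k_flips, replace=False)))
    cell_edits = [ModelEdit.set_rule("IN1", "1"), ModelEdit.set_rule("IN2", "1")]
    cell_edits += [ModelEdit.set_link_operator(n, OR_NOT) for n in flip_nodes]
    planted = apply_edits(generic, cell_edits)
    states = stable_states(planted)
    if len(states) != 1:
        raise SynthError(f"planted model has {len(states)} stable states; expected 1")
    truth = states[0]

    truth_prof, lit_prof, omics_prof = gen_profiles(
        planted, flip_fraction=flip_fraction, na_fraction=na_fraction,
        lit_size=lit_size, seed=int(rng.integers(0, 2 ** 31 - 1)),
        cell_line=cell_line, truth_state=truth)

    panel = make_panel({f"D{i}": f"TGT{i}" for i in range(1, n_drugs + 1)},
                       network=net,
                       full_names={f"D{i}": f"TGT{i} inhibitor"
                                   for i in range(1, n_drugs + 1)})
    planted_pairs = frozenset({("D1", "D2"), ("D3", "D4")})
    records = gen_screen(panel, planted_pairs, n_doses=n_doses,
                         excess_depth=excess_depth, noise_sd=noise_sd,
                         seed=int(rng.integers(0, 2 ** 31 - 1)),
                         cell_line=cell_line)
    return SyntheticBundle(
        network=net, generic_model=generic, planted_model=planted,
        planted_flips=flip_nodes, truth_state=truth,
        profile_truth=truth_prof, profile_literature=lit_prof,
        profile_omics=omics_prof, panel=panel, screen_records=tuple(records),
        planted_synergies=planted_pairs, bottleneck_node="M",
        params=dict(n_nodes=n_nodes, n_drugs=n_drugs, k_flips=k_flips,
                    flip_fraction=flip_fraction, na_fraction=na_fraction,
                    lit_size=lit_size, n_doses=n_doses,
                    excess_depth=excess_depth, noise_sd=noise_sd),
        seed=seed)


def gen_profiles(planted_model: LogicalModel, flip_fraction: float = 0.0,
                 na_fraction: float = 0.0, lit_size: int = 9, seed: int = 0,
                 cell_line: str = "SYN-1", truth_state: dict | None = None):
    """Derive (truth, literature-like, omics-like) profiles from the planted state.

    The omics-like profile covers every Boolean node but inverts a
    ``flip_fraction`` of values and blanks an ``na_fraction`` (emulating
    inference error and dropout); the literature-like profile is the exact
    truth restricted to ``lit_size`` randomly chosen nodes (emulating
    sparse, high-quality curation).
    """
    for frac in (flip_fraction, na_fraction):
        if not 0.0 <= frac <= 1.0:
            raise SynthError(f"fraction {frac} outside [0, 1]")
    if truth_state is None:
        states = stable_states(planted_model)
        if len(states) != 1:
            raise SynthError("planted model must have a unique stable state")
        truth_state = states[0]
    rng = np.random.default_rng(seed)
    bool_nodes = sorted(n for n in planted_model.network.nodes
                        if planted_model.max_level(n) == 1)
    truth_vals = {n: int(truth_state[n] >= 1) for n in bool_nodes}
    truth_prof = ActivityProfile(cell_line=cell_line, values=dict(truth_vals),
                                 source="truth")

    omics_vals = dict(truth_vals)
    n_flip = int(round(flip_fraction * len(bool_nodes)))
    for i in rng.choice(len(bool_nodes), size=n_flip, replace=False):
        n = bool_nodes[i]
        omics_vals[n] = 1 - omics_vals[n]
    n_na = int(round(na_fraction * len(bool_nodes)))
    for i in rng.choice(len(bool_nodes), size=n_na, replace=False):
        omics_vals[bool_nodes[i]] = None
    omics_prof = ActivityProfile(cell_line=cell_line, values=omics_vals,
                                 source="omics")

    lit_size = min(lit_size, len(bool_nodes))
    keep = {bool_nodes[i] for i in rng.choice(len(bool_nodes), size=lit_size,
                                              replace=False)}
    lit_vals = {n: (truth_vals[n] if n in keep else None) for n in bool_nodes}
    lit_prof = ActivityProfile(cell_line=cell_line, values=lit_vals,
                               source="literature")
    return truth_prof, lit_prof, omics_prof


def gen_screen(panel: DrugPanel, planted_synergies, n_doses: int = 3,
               excess_depth: float = -0.2, noise_sd: float = 0.0, seed: int = 0,
               cell_line: str = "SYN-1") -> list[ScreenRecord]:
    """Dose-matrix screen with the planted pairs showing a flat HSA excess of
    ``excess_depth`` (plus Gaussian noise) and all other pairs an excess of 0."""
    planted = {tuple(sorted(p)) for p in planted_synergies}
    unknown = planted - set(map(tuple, map(sorted, panel.pairs())))
    if unknown:
        raise SynthError(f"planted pairs not in panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    doses = [round(2.0 ** (i - n_doses + 1), 6) for i in range(n_doses)]  # ..0.25,0.5,1
    offsets = {d: float(rng.uniform(-0.05, 0.05)) for d in panel.drugs}

    def single(drug, dose):
        return 1.0 - 0.4 * dose + offsets[drug]  # monotone decreasing in dose

    records = []
    for a, b in panel.pairs():
        depth = excess_depth if (a, b) in planted else 0.0
        single_a = {d: single(a, d) for d in doses}
        single_b = {d: single(b, d) for d in doses}
        combo = {}
        for da in doses:
            for db in doses:
                noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                combo[(da, db)] = min(single_a[da], single_b[db]) + depth + noise
        records.append(ScreenRecord(cell_line=cell_line, drug_a=a, drug_b=b,
                                    single_a=single_a, single_b=single_b,
                                    combo=combo))
    return records


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict:
    """Write the bundle as plain-text files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "panel": out / "panel.tsv",
        "profile_literature": out / "profile_literature.tsv",
        "profile_omics": out / "profile_omics.tsv",
        "screen": out / "screen.csv",
        "edits": out / "edits.yaml",
        "truth": out / "truth.json",
    }
    write_network(bundle.network, paths["network"])
    write_panel(bundle.panel, paths["panel"])
    write_profile(bundle.profile_literature, paths["profile_literature"])
    write_profile(bundle.profile_omics, paths["profile_omics"])
    write_screen_csv(bundle.screen_records, paths["screen"])
    from .model import edits_to_yaml
    edits_to_yaml(bundle.generic_model.edit_log, paths["edits"])
    truth = {
        "cell_line": bundle.profile_truth.cell_line,
        "seed": bundle.seed,
        "params": bundle.params,
        "planted_flips": list(bundle.planted_flips),
        "planted_synergies": sorted(map(list, bundle.planted_synergies)),
        "bottleneck_node": bundle.bottleneck_node,
        "stable_state": {k: int(v) for k, v in sorted(bundle.truth_state.items())},
    }
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
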