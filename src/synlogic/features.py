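"""Structural node features and feature-importance ranking.

Features are computed on the directed graph, ignoring edge signs:

* out-degree;
* betweenness centrality (fraction of directed shortest paths through the
  node, endpoints excluded);
* closeness centrality, by default in the harmonic form (mean inverse
  distance over incoming paths) which is well defined on disconnected
  digraphs;
* the pathway cross-talk inhibition index (PCI): the relative drop in
  global efficiency when the node and its incident edges are removed,
  PCI(v) = (E(G) - E(G \\ v)) / E(G), with global efficiency
  E = mean over ordered pairs of 1/d(i, j) (unreachable pairs contribute 0).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .network import RegulatoryNetwork


class FeatureError(ValueError):
    pass


def _as_digraph(net) -> nx.DiGraph:
    if isinstance(net, RegulatoryNetwork):
        return net.to_networkx()
    return nx.DiGraph(net)


def global_efficiency(net) -> float:
    """Directed global efficiency: mean inverse shortest-path length."""
    g = _as_digraph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise FeatureError("global efficiency needs at least 2 nodes")
    total = 0.0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for target, d in dists.items():
            if d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def pci(net, node: str) -> float:
    """Relative efficiency loss on removing ``node`` (and incident edges)."""
    g = _as_digraph(net)
    if node not in g:
        raise FeatureError(f"unknown node {node!r}")
    e_full = global_efficiency(g)
    if e_full == 0:
        raise FeatureError("PCI undefined: network has zero efficiency")
    h = g.copy()
    h.remove_node(node)
    return (e_full - global_efficiency(h)) / e_full


def centralities(net, closeness_mode: str = "harmonic") -> pd.DataFrame:
    """Per-node betweenness, closeness and out-degree."""
    g = _as_digraph(net)
    n = g.number_of_nodes()
    betw = nx.betweenness_centrality(g, normalized=True)
    if closeness_mode == "harmonic":
        close = {k: v / (n - 1) if n > 1 else 0.0
                 for k, v in nx.harmonic_centrality(g).items()}
    elif closeness_mode == "classic":
        close = nx.closeness_centrality(g)
    else:
        raise FeatureError(f"unknown closeness mode {closeness_mode!r}")
    return pd.DataFrame({
        "out_degree": {v: g.out_degree(v) for v in g.nodes},
        "betweenness": betw,
        "closeness": close,
    }).sort_index()


def node_feature_table(net, labels=None, annotations=None,
                       closeness_mode: str = "harmonic") -> pd.DataFrame:
    """Feature table: structural columns plus optional pass-through annotations
    and a high/low influence ``label`` column."""
    table = centralities(net, closeness_mode=closeness_mode)
    table["pci"] = [pci(net, v) for v in table.index]
    if annotations is not None:
        ann = pd.DataFrame(annotations)
        table = table.join(ann, how="left")
    if labels is not None:
        if isinstance(labels, (set, frozenset)):
            table["label"] = [("high" if v in labels else "low") for v in table.index]
        else:
            table["label"] = pd.Series(dict(labels))
    return table


def importance_ranking(table: pd.DataFrame, labels=None, balanced: bool = False,
                       seed: int = 0, n_repeats: int = 10,
                       n_estimators: int = 200) -> pd.DataFrame:
    """Gini (impurity) feature importances from a random forest, averaged over
    ``n_repeats`` seeded fits; ``balanced`` subsamples the majority class."""
    from sklearn.ensemble import RandomForestClassifier

    if labels is None:
        if "label" not in table.columns:
            raise FeatureError("labels required (argument or 'label' column)")
        y = table["label"]
        x = table.drop(columns=["label"])
    else:
        y = pd.Series(labels, index=table.index) if not isinstance(labels, pd.Series) else labels
        x = table.drop(columns=[c for c in ("label",) if c in table.columns])
    x = x.astype(float)
    y = pd.Series(y).astype(str)
    if y.nunique() < 2:
        raise FeatureError("importance ranking needs at least two classes")
    rng = np.random.default_rng(seed)
    importances = np.zeros(x.shape[1])
    for rep in range(n_repeats):
        xi, yi = x, y
        if balanced:
            counts = y.value_counts()
            n_min = counts.min()
            keep_idx = []
            for cls in counts.index:
                members = y.index[y == cls].to_numpy()
                picked = rng.choice(members, size=n_min, replace=False)
                keep_idx.extend(picked)
            xi, yi = x.loc[keep_idx], y.loc[keep_idx]
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2 ** 31 - 1)),
        ).fit(xi.to_numpy(), yi.to_numpy())
        importances += clf.feature_importances_
    importances /= n_repeats
    out = pd.DataFrame({"feature": x.columns, "importance": importances})
    return out.sort_values(["importance", "feature"],
                           ascending=[False, True]).reset_index(drop=True)


def feature_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the numeric feature columns."""
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise FeatureError("correlations need at least 3 rows")
    return numeric.corr(method="pearson")
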