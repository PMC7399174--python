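"""Independent brute-force oracles used to pin implementation correctness.

Everything here is deliberately naive: full state-space enumeration,
hand-rolled Tarjan SCCs over an explicit successor map, Floyd-Warshall
distances and explicit shortest-path counting.  None of it shares code
paths with the package implementations it checks.
"""

import itertools


def enumerate_states(model, clamps=None):
    m = model.clamped(clamps) if clamps else model
    names = sorted(m.network.nodes)
    for combo in itertools.product(*(range(m.max_level(n) + 1) for n in names)):
        yield dict(zip(names, combo))


def brute_force_stable_states(model, clamps=None):
    m = model.clamped(clamps) if clamps else model
    names = sorted(m.network.nodes)
    out = []
    for state in enumerate_states(m):
        if all(m.rules[n].next_value(state) == state[n] for n in names):
            out.append(state)
    out.sort(key=lambda s: tuple(s[n] for n in names))
    return out


def brute_force_async_attractors(model, clamps=None):
    """Terminal SCCs of the full asynchronous transition graph (own Tarjan)."""
    m = model.clamped(clamps) if clamps else model
    names = sorted(m.network.nodes)
    clamp_map = dict(clamps or {})
    ranges = [(range(clamp_map[n], clamp_map[n] + 1) if n in clamp_map
               else range(m.max_level(n) + 1)) for n in names]
    rules = [m.rules[n] for n in names]
    succ = {}
    for combo in itertools.product(*ranges):
        state = dict(zip(names, combo))
        nxt = []
        for i in range(len(names)):
            target = rules[i].next_value(state)
            if target != combo[i]:
                step = combo[i] + (1 if target > combo[i] else -1)
                nxt.append(combo[:i] + (step,) + combo[i + 1:])
        succ[combo] = nxt

    # iterative Tarjan
    index = {}
    lowlink = {}
    on_stack = set()
    stack = []
    sccs = []
    counter = [0]
    for root in succ:
        if root in index:
            continue
        work = [(root, iter(succ[root]))]
        index[root] = lowlink[root] = counter[0]
        counter[0] += 1
        stack.append(root)
        on_stack.add(root)
        while work:
            v, it = work[-1]
            advanced = False
            for w in it:
                if w not in index:
                    index[w] = lowlink[w] = counter[0]
                    counter[0] += 1
                    stack.append(w)
                    on_stack.add(w)
                    work.append((w, iter(succ[w])))
                    advanced = True
                    break
                if w in on_stack:
                    lowlink[v] = min(lowlink[v], index[w])
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                lowlink[parent] = min(lowlink[parent], lowlink[v])
            if lowlink[v] == index[v]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.append(w)
                    if w == v:
                        break
                sccs.append(frozenset(comp))

    member_of = {}
    for comp in sccs:
        for s in comp:
            member_of[s] = comp
    terminal = []
    for comp in sccs:
        if all(member_of[w] is comp for s in comp for w in succ[s]):
            terminal.append(sorted(comp))
    out = []
    for comp in terminal:
        states = tuple(dict(zip(names, c)) for c in comp)
        out.append(("stable_state" if len(states) == 1 else "complex", states))
    out.sort(key=lambda a: tuple(a[1][0][n] for n in names))
    return out


# ---------------------------------------------------------------------------
# graph-feature oracles


def _digraph_dists(nodes, edge_set):
    inf = float("inf")
    d = {(u, v): (0 if u == v else inf) for u in nodes for v in nodes}
    for u, v in edge_set:
        d[(u, v)] = 1
    for k in nodes:
        for i in nodes:
            ik = d[(i, k)]
            if ik == inf:
                continue
            for j in nodes:
                if ik + d[(k, j)] < d[(i, j)]:
                    d[(i, j)] = ik + d[(k, j)]
    return d


def efficiency_oracle(nodes, edge_set):
    nodes = list(nodes)
    n = len(nodes)
    d = _digraph_dists(nodes, edge_set)
    total = sum(1.0 / d[(u, v)] for u in nodes for v in nodes
                if u != v and d[(u, v)] != float("inf"))
    return total / (n * (n - 1))


def pci_oracle(nodes, edge_set, node):
    e_full = efficiency_oracle(nodes, edge_set)
    rest = [v for v in nodes if v != node]
    rest_edges = {(u, v) for u, v in edge_set if node not in (u, v)}
    return (e_full - efficiency_oracle(rest, rest_edges)) / e_full


def harmonic_closeness_oracle(nodes, edge_set):
    nodes = list(nodes)
    n = len(nodes)
    d = _digraph_dists(nodes, edge_set)
    out = {}
    for v in nodes:
        s = sum(1.0 / d[(u, v)] for u in nodes
                if u != v and d[(u, v)] != float("inf"))
        out[v] = s / (n - 1) if n > 1 else 0.0
    return out


def betweenness_oracle(nodes, edge_set):
    """Directed betweenness by explicit shortest-path counting."""
    nodes = list(nodes)
    n = len(nodes)
    d = _digraph_dists(nodes, edge_set)
    succ = {u: [v for v in nodes if (u, v) in edge_set] for u in nodes}

    def count_paths(s, t):
        # number of shortest s->t paths through each node
        if s == t or d[(s, t)] == float("inf"):
            return 0, {}
        npaths = {s: 1}
        through = {}
        order = sorted(nodes, key=lambda v: d[(s, v)])
        for v in order:
            if v == s or d[(s, v)] == float("inf"):
                continue
            npaths[v] = sum(npaths.get(u, 0) for u in nodes
                            if (u, v) in edge_set and d[(s, u)] + 1 == d[(s, v)])
        total = npaths.get(t, 0)
        if total == 0:
            return 0, {}
        # paths through v = npaths(s->v) * npaths(v->t) when on a shortest path
        for v in nodes:
            if v in (s, t):
                continue
            if d[(s, v)] != float("inf") and d[(v, t)] != float("inf") \
                    and d[(s, v)] + d[(v, t)] == d[(s, t)]:
                npaths_vt = _count_simple(s=v, t=t, nodes=nodes, edge_set=edge_set, d=d)
                through[v] = npaths.get(v, 0) * npaths_vt
        return total, through

    def _count_simple(s, t, nodes, edge_set, d):
        npaths = {s: 1}
        order = sorted(nodes, key=lambda v: d[(s, v)])
        for v in order:
            if v == s or d[(s, v)] == float("inf"):
                continue
            npaths[v] = sum(npaths.get(u, 0) for u in nodes
                            if (u, v) in edge_set and d[(s, u)] + 1 == d[(s, v)])
        return npaths.get(t, 0)

    raw = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            total, through = count_paths(s, t)
            if total == 0:
                continue
            for v, cnt in through.items():
                raw[v] += cnt / total
    norm = (n - 1) * (n - 2) if n > 2 else 1
    return {v: raw[v] / norm for v in nodes}
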