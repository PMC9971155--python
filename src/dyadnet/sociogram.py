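"""Weighted sociograms: graph construction, layout, and community detection.

Nodes are individuals (females drawn red, males blue), edges carry the
simple-ratio index of every dyad with a positive index. Layout uses the
weighted Fruchterman-Reingold algorithm; communities minimize the
Reichardt-Bornholdt Potts Hamiltonian

    H = - sum_{i<j} (w_ij - gamma * s_i * s_j / (2m)) * delta(c_i, c_j)

with the configuration null model, by seeded simulated annealing run per
connected component (edgeless components are singleton communities).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import igraph as ig
import networkx as nx
import numpy as np

from .association import AssociationMatrix
from .data_model import Individual

logger = logging.getLogger("dyadnet")

__all__ = [
    "SocialGraph",
    "build_graph",
    "layout_fr",
    "spinglass_communities",
    "potts_hamiltonian",
    "export_graphml",
    "export_edgelist",
    "draw_sociogram",
]


@dataclass
class SocialGraph:
    graph: nx.Graph
    measure: str
    layout: Optional[Dict] = None
    communities: Optional[Dict] = None
    hamiltonian: Optional[float] = None


def build_graph(matrix: AssociationMatrix, roster: Sequence[Individual]) -> SocialGraph:
    """Graph with one node per roster id and one edge per positive-SRI dyad."""
    sex = {ind.id: ind.sex for ind in roster if not ind.excluded}
    missing = set(matrix.ids) - set(sex)
    if missing:
        raise ValueError(f"matrix ids missing from roster: {sorted(missing)}")
    G = nx.Graph()
    for iid in matrix.ids:
        G.add_node(iid, sex=sex[iid])
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = matrix.values[i, j]
            if np.isfinite(w) and w > 0:
                G.add_edge(matrix.ids[i], matrix.ids[j], weight=float(w))
    return SocialGraph(graph=G, measure=matrix.measure)


def layout_fr(sg: SocialGraph, seed: int = 0, niter: int = 500) -> Dict:
    """Weighted Fruchterman-Reingold coordinates, deterministic given seed."""
    G = sg.graph
    nodes = list(G.nodes)
    if len(nodes) == 0:
        sg.layout = {}
        return sg.layout
    if len(nodes) == 1:
        sg.layout = {nodes[0]: (0.0, 0.0)}
        return sg.layout
    g = ig.Graph()
    g.add_vertices(len(nodes))
    index = {v: k for k, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in G.edges]
    g.add_edges(edges)
    weights = [G.edges[u, v]["weight"] for u, v in G.edges] or None
    rng = np.random.default_rng(seed)
    seed_coords = rng.uniform(-1, 1, size=(len(nodes), 2)).tolist()
    import random as _pyrandom

    ig.set_random_number_generator(_pyrandom.Random(int(seed) & 0x7FFFFFFF))
    coords = g.layout_fruchterman_reingold(weights=weights, niter=niter, seed=seed_coords)
    ig.set_random_number_generator(None)  # restore igraph's default RNG
    sg.layout = {v: (float(coords[index[v]][0]), float(coords[index[v]][1])) for v in nodes}
    return sg.layout


# ---------------------------------------------------------------------------
# Spinglass community detection (Potts model, configuration null)


def potts_hamiltonian(G: nx.Graph, labels: Dict, gamma: float = 1.0) -> float:
    """Total Hamiltonian, null model computed within each connected component."""
    total = 0.0
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        m = sum(G.edges[u, v]["weight"] for u, v in G.edges(nodes) if u in comp and v in comp) or 0.0
        if m <= 0:
            continue
        strength = {v: sum(G.edges[v, nb]["weight"] for nb in G[v]) for v in nodes}
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                if labels[u] != labels[v]:
                    continue
                w = G.edges[u, v]["weight"] if G.has_edge(u, v) else 0.0
                total -= w - gamma * strength[u] * strength[v] / (2.0 * m)
    return total


def _anneal_component(
    W: np.ndarray,
    gamma: float,
    max_spins: int,
    rng: np.random.Generator,
    t_start: float,
    cooling: float,
    t_stop: float,
) -> Tuple[np.ndarray, float]:
    """Simulated annealing + greedy descent for one connected component."""
    n = W.shape[0]
    strength = W.sum(axis=1)
    m = strength.sum() / 2.0
    B = W - gamma * np.outer(strength, strength) / (2.0 * m)
    np.fill_diagonal(B, 0.0)
    n_spins = min(max_spins, n)
    labels = np.arange(n) % n_spins
    rng.shuffle(labels)

    def spin_sums(lab):
        S = np.zeros((n, n_spins))
        for i in range(n):
            S[:, lab[i]] += B[:, i]
        return S

    S = spin_sums(labels)  # S[i, c] = sum of B[i, j] over j with label c (includes j=i term, B_ii=0)
    current = -0.5 * sum(S[i, labels[i]] for i in range(n))
    best = current
    best_labels = labels.copy()

    T = t_start
    while T > t_stop:
        for i in rng.permutation(n):
            c = labels[i]
            c_new = int(rng.integers(n_spins))
            if c_new == c:
                continue
            dH = -(S[i, c_new] - S[i, c])
            if dH < 0 or rng.random() < np.exp(-dH / T):
                labels[i] = c_new
                S[:, c] -= B[:, i]
                S[:, c_new] += B[:, i]
                current += dH
                if current < best - 1e-12:
                    best = current
                    best_labels = labels.copy()
        T *= cooling

    # greedy descent from the best state until no single move improves
    labels = best_labels.copy()
    S = spin_sums(labels)
    current = best
    improved = True
    while improved:
        improved = False
        for i in range(n):
            c = labels[i]
            gains = -(S[i] - S[i, c])
            c_new = int(np.argmin(gains))
            if gains[c_new] < -1e-12:
                labels[i] = c_new
                S[:, c] -= B[:, i]
                S[:, c_new] += B[:, i]
                current += gains[c_new]
                improved = True
    return labels, float(current)


def spinglass_communities(
    sg: SocialGraph,
    gamma: float = 1.0,
    max_spins: int = 25,
    seed: int = 0,
    t_start: float = 1.0,
    cooling: float = 0.99,
    t_stop: float = 0.01,
    restarts: int = 3,
) -> Tuple[Dict, float]:
    """Community labels minimizing the Potts Hamiltonian; deterministic given seed.

    Disconnected graphs are processed per component (logged); components
    without edges become singleton communities.
    """
    G = sg.graph
    components = list(nx.connected_components(G))
    if len(components) > 1:
        logger.info("spinglass: %d connected components processed independently", len(components))
    labels: Dict = {}
    total_h = 0.0
    next_label = 0
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 17])
    streams = iter(ss.spawn(len(components) * restarts + 1))
    for comp in sorted(components, key=lambda c: sorted(c)[0]):
        nodes = sorted(comp)
        if len(nodes) == 1 or G.subgraph(nodes).number_of_edges() == 0:
            for v in nodes:
                labels[v] = next_label
                next_label += 1
            continue
        n = len(nodes)
        W = np.zeros((n, n))
        pos = {v: k for k, v in enumerate(nodes)}
        for u, v, data in G.subgraph(nodes).edges(data=True):
            W[pos[u], pos[v]] = W[pos[v], pos[u]] = data["weight"]
        best_lab, best_h = None, np.inf
        for _ in range(restarts):
            rng = np.random.default_rng(next(streams))
            lab, h = _anneal_component(W, gamma, max_spins, rng, t_start, cooling, t_stop)
            if h < best_h:
                best_h, best_lab = h, lab
        # relabel to consecutive integers
        remap: Dict = {}
        for v in nodes:
            c = int(best_lab[pos[v]])
            if c not in remap:
                remap[c] = next_label
                next_label += 1
            labels[v] = remap[c]
        total_h += best_h
    sg.communities = labels
    sg.hamiltonian = total_h
    return labels, total_h


# ---------------------------------------------------------------------------
# Export


def export_graphml(sg: SocialGraph, path) -> None:
    G = sg.graph.copy()
    for v in G.nodes:
        if sg.communities is not None:
            G.nodes[v]["community"] = int(sg.communities[v])
        if sg.layout is not None and v in sg.layout:
            G.nodes[v]["x"] = float(sg.layout[v][0])
            G.nodes[v]["y"] = float(sg.layout[v][1])
    nx.write_graphml(G, path)


def export_edgelist(sg: SocialGraph, path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"member_a{delimiter}member_b{delimiter}weight\n")
        for u, v, data in sorted(sg.graph.edges(data=True)):
            a, b = (u, v) if u < v else (v, u)
            fh.write(f"{a}{delimiter}{b}{delimiter}{data['weight']!r}\n")


def import_edgelist(path, measure: str = "party10m", delimiter: str = ",") -> SocialGraph:
    G = nx.Graph()
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b, w = line.strip().split(delimiter)
            G.add_edge(a, b, weight=float(w))
    return SocialGraph(graph=G, measure=measure)


def draw_sociogram(sg: SocialGraph, path) -> None:
    """Vector figure: red female / blue male nodes, edge width by tie strength."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if sg.layout is None:
        layout_fr(sg)
    fig, ax = plt.subplots(figsize=(6, 6))
    for u, v, data in sg.graph.edges(data=True):
        x = [sg.layout[u][0], sg.layout[v][0]]
        y = [sg.layout[u][1], sg.layout[v][1]]
        ax.plot(x, y, color="0.6", linewidth=0.3 + 4.0 * data["weight"], zorder=1)
    colors = {"F": "tab:red", "M": "tab:blue"}
    for v, data in sg.graph.nodes(data=True):
        x, y = sg.layout[v]
        ax.scatter([x], [y], s=160, c=colors.get(data.get("sex", "F"), "gray"), zorder=2, edgecolors="black")
        ax.annotate(v, (x, y), fontsize=5, ha="center", va="center", zorder=3)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
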