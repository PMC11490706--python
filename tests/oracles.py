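"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as directly as possible (explicit loops, flood
fill, networkx path chasing) and deliberately shares no code with the
package modules it checks.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def triangle_oracle(counts, values, dark_background=True):
    """Scan every bin between peak and tail; maximize line distance."""
    counts = list(map(int, counts))
    values = list(map(float, values))
    if not dark_background:
        counts = counts[::-1]
        values = values[::-1]
    peak = counts.index(max(counts))
    occupied = [i for i, c in enumerate(counts) if c > 0]
    tail = occupied[-1]
    assert tail > peak, "degenerate histogram"
    dx, dh = tail - peak, counts[tail] - counts[peak]
    norm = math.hypot(dx, dh)
    best_i, best_d = None, -1.0
    for i in range(peak + 1, tail):
        d = abs(dh * (i - peak) - dx * (counts[i] - counts[peak])) / norm
        if d > best_d + 1e-12:
            best_d, best_i = d, i
    return values[peak] if best_i is None else values[best_i]


def disk_majority_oracle(mask: np.ndarray, radius: float) -> np.ndarray:
    """Per-pixel majority over the Euclidean disk, ties to foreground."""
    ny, nx_ = mask.shape
    r = int(math.floor(radius))
    out = np.zeros_like(mask, dtype=bool)
    for y in range(ny):
        for x in range(nx_):
            fg = tot = 0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dy * dy + dx * dx > radius * radius:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < ny and 0 <= xx < nx_:
                        tot += 1
                        fg += bool(mask[yy, xx])
            out[y, x] = 2 * fg >= tot
    return out


def flood_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by explicit stack-based flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    ny, nx_ = mask.shape
    for y in range(ny):
        for x in range(nx_):
            if not mask[y, x] or seen[y, x]:
                continue
            comp, stack = set(), [(y, x)]
            seen[y, x] = True
            while stack:
                cy, cx = stack.pop()
                comp.add((cy, cx))
                for dy, dx in NB8:
                    yy, xx = cy + dy, cx + dx
                    if 0 <= yy < ny and 0 <= xx < nx_ and mask[yy, xx] and not seen[yy, xx]:
                        seen[yy, xx] = True
                        stack.append((yy, xx))
            comps.append(comp)
    return comps


def _step(p, q):
    return math.sqrt(2.0) if (p[0] != q[0] and p[1] != q[1]) else 1.0


def skeleton_graph_oracle(P: np.ndarray):
    """Node count, branch count, and branch α multiset via networkx.

    Same conventions as the production analyzer (neighbor-count pixel
    classes, 8-adjacent junction merging, anchor-inclusive α) but computed
    through an entirely different route: a pixel graph whose node pixels are
    deleted, leaving slab chains as connected components.
    """
    ny, nx_ = P.shape
    pix = [(y, x) for y in range(ny) for x in range(nx_) if P[y, x]]
    G = nx.Graph()
    G.add_nodes_from(pix)
    for y, x in pix:
        for dy, dx in NB8:
            q = (y + dy, x + dx)
            if 0 <= q[0] < ny and 0 <= q[1] < nx_ and P[q]:
                G.add_edge((y, x), q)

    kind = {}
    for p in pix:
        d = G.degree(p)
        kind[p] = "endpoint" if d <= 1 else ("slab" if d == 2 else "junction")

    junction_pixels = [p for p in pix if kind[p] == "junction"]
    clusters = list(nx.connected_components(G.subgraph(junction_pixels)))
    cluster_of = {}
    for i, comp in enumerate(clusters):
        for p in comp:
            cluster_of[p] = i
    n_nodes = len(clusters) + sum(1 for p in pix if kind[p] == "endpoint")

    slab_pixels = [p for p in pix if kind[p] == "slab"]
    S = G.subgraph(slab_pixels)
    alphas = []
    n_branches = 0
    for comp in nx.connected_components(S):
        sub = S.subgraph(comp)
        ends = [p for p in comp if sub.degree(p) <= 1]
        if not ends:  # pure slab ring
            cycle = nx.find_cycle(sub)
            n_branches += 1
            alphas.append(sum(_step(u, v) for u, v in cycle))
            continue
        if len(comp) == 1:
            # lone slab pixel: both of its neighbors are node anchors
            p = next(iter(comp))
            anchors = [q for q in G.neighbors(p) if kind[q] != "slab"]
            path = [anchors[0], p, anchors[1]]
        else:
            chain = nx.shortest_path(sub, ends[0], ends[1])
            # anchors: each chain end's neighbor outside the chain is a node pixel
            first_anchor = [q for q in G.neighbors(chain[0]) if kind[q] != "slab"]
            last_anchor = [q for q in G.neighbors(chain[-1]) if kind[q] != "slab"]
            path = [first_anchor[0], *chain, last_anchor[0]]
        n_branches += 1
        alphas.append(sum(_step(path[i], path[i + 1]) for i in range(len(path) - 1)))

    # zero-slab branches: endpoint pixel adjacent to a node pixel
    for p in pix:
        if kind[p] != "endpoint":
            continue
        nbrs = list(G.neighbors(p))
        if not nbrs:
            continue
        q = nbrs[0]
        if kind[q] == "slab":
            continue
        if kind[q] == "endpoint" and q < p:
            continue
        n_branches += 1
        alphas.append(_step(p, q))

    return n_nodes, n_branches, sorted(round(a, 9) for a in alphas)
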