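"""1-px skeletons and their branch graphs.

``skeletonize`` thins a binary mask to a 1-px centerline (Zhang two-
subiteration thinning, 8-connected foreground).  ``build_skeleton_graph``
converts the skeleton into a graph of endpoint/junction nodes and measured
branches, reproducing the classic skeleton-analyzer semantics:

* pixels are classified by their 8-neighbor count — 1 → endpoint, 2 → slab,
  >= 3 → junction pixel;
* 8-adjacent junction pixels merge into a single junction node;
* a branch is a maximal run of slab pixels between two node anchor pixels;
  its geodesic length α sums unit steps for orthogonal moves and √2 steps for
  diagonal moves, anchor steps included, and its chord β is the Euclidean
  distance between the two anchor (terminal) pixels, so α >= β always.

Branches are emitted in raster-scan order of their first slab pixel, making
exported tables deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import NotASkeleton
from .image import BinaryMask

__all__ = ["Node", "Branch", "SkeletonGraph", "skeletonize", "build_skeleton_graph"]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Thin a mask to its 1-px, 8-connected skeleton.

    The output is a subset of the input, preserves the connected-component
    count, and is idempotent on already-thin input.  An empty mask yields an
    empty skeleton.
    """
    return mask.with_step(
        _sk_skeletonize(mask.pixels, method="zhang"), "skeletonize(zhang)"
    )


@dataclass(frozen=True)
class Node:
    node_id: int
    member_pixels: tuple[tuple[int, int], ...]
    centroid: tuple[float, float]  # (row, col)
    kind: str  # "endpoint" | "junction"


@dataclass(frozen=True)
class Branch:
    branch_id: int
    path_pixels: tuple[tuple[int, int], ...]  # anchors included, ordered
    end_node_a: int | None
    end_node_b: int | None
    alpha_um: float
    beta_um: float
    is_loop: bool

    # populated by the builder via object.__setattr__ (frozen dataclass)
    _endpointish: bool = field(default=False, repr=False, compare=False)

    @property
    def has_endpoint_terminal(self) -> bool:
        """True when either terminal is an endpoint (degree-1) node."""
        return self._endpointish


@dataclass
class SkeletonGraph:
    nodes: list[Node]
    branches: list[Branch]
    pixel_size_um: float

    def nodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": [n.node_id for n in self.nodes],
                "kind": [n.kind for n in self.nodes],
                "centroid_row": [n.centroid[0] for n in self.nodes],
                "centroid_col": [n.centroid[1] for n in self.nodes],
                "n_pixels": [len(n.member_pixels) for n in self.nodes],
            }
        )

    def branches_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch_id": [b.branch_id for b in self.branches],
                "end_node_a": [b.end_node_a for b in self.branches],
                "end_node_b": [b.end_node_b for b in self.branches],
                "alpha_um": [b.alpha_um for b in self.branches],
                "beta_um": [b.beta_um for b in self.branches],
                "is_loop": [b.is_loop for b in self.branches],
            }
        )


def _step_length(p: tuple[int, int], q: tuple[int, int]) -> float:
    return np.sqrt(2.0) if (p[0] != q[0] and p[1] != q[1]) else 1.0


def _path_length_px(path: list[tuple[int, int]], closed: bool = False) -> float:
    total = sum(_step_length(path[i], path[i + 1]) for i in range(len(path) - 1))
    if closed and len(path) > 1:
        total += _step_length(path[-1], path[0])
    return total


def build_skeleton_graph(
    skeleton: BinaryMask, pixel_size_um: float | None = None, validate: bool = True
) -> SkeletonGraph:
    """Convert a 1-px skeleton into nodes and measured branches.

    Raises :class:`NotASkeleton` when a junction cluster contains a full 2×2
    block yet anchors no branch end at all — the signature of a mask that was
    never thinned (free-standing thick blobs, width-2 bars) as opposed to a
    thick junction node legitimately left by thinning a sharp fold or
    crossing.
    """
    px_um = pixel_size_um if pixel_size_um is not None else skeleton.pixel_size_um
    P = skeleton.pixels
    ny, nx = P.shape

    kernel = np.ones((3, 3), dtype=np.int64)
    kernel[1, 1] = 0
    nb_count = ndi.convolve(P.astype(np.int64), kernel, mode="constant", cval=0)
    endpoint_px = P & (nb_count <= 1)
    slab_px = P & (nb_count == 2)
    junction_px = P & (nb_count >= 3)

    # node_id_map[r, c] >= 0 marks a node pixel with its node id.
    node_id_map = np.full(P.shape, -1, dtype=np.int64)
    nodes: list[Node] = []

    jl, n_j = ndi.label(junction_px, structure=np.ones((3, 3)))
    if n_j:
        jr, jc = np.nonzero(junction_px)  # raster order, so members stay sorted
        labs = jl[jr, jc]
        order = np.argsort(labs, kind="stable")
        jr, jc, labs = jr[order], jc[order], labs[order]
        starts = np.searchsorted(labs, np.arange(1, n_j + 2))
        for lab in range(n_j):
            rows = jr[starts[lab] : starts[lab + 1]]
            cols = jc[starts[lab] : starts[lab + 1]]
            members = tuple((int(r), int(c)) for r, c in zip(rows, cols))
            nid = len(nodes)
            nodes.append(
                Node(nid, members, (float(rows.mean()), float(cols.mean())), "junction")
            )
            node_id_map[rows, cols] = nid
    for r, c in zip(*np.nonzero(endpoint_px)):
        nid = len(nodes)
        nodes.append(Node(nid, ((int(r), int(c)),), (float(r), float(c)), "endpoint"))
        node_id_map[r, c] = nid

    def true_neighbors(r: int, c: int) -> list[tuple[int, int]]:
        out = []
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and P[rr, cc]:
                out.append((rr, cc))
        return out

    branches: list[Branch] = []
    visited = np.zeros(P.shape, dtype=bool)
    incident_ends: dict[int, int] = {}

    def emit(
        path: list[tuple[int, int]],
        na: int | None,
        nb: int | None,
        alpha_px: float,
        beta_px: float,
        is_loop: bool,
        endpointish: bool,
    ) -> None:
        b = Branch(
            branch_id=len(branches),
            path_pixels=tuple(path),
            end_node_a=na,
            end_node_b=nb,
            alpha_um=alpha_px * px_um,
            beta_um=beta_px * px_um,
            is_loop=is_loop,
        )
        object.__setattr__(b, "_endpointish", endpointish)
        branches.append(b)
        for n in (na, nb):
            if n is not None:
                incident_ends[n] = incident_ends.get(n, 0) + 1

    # --- branches with at least one slab pixel, raster order of first slab ---
    slab_rows, slab_cols = np.nonzero(slab_px)
    for r0, c0 in zip(slab_rows, slab_cols):
        if visited[r0, c0]:
            continue
        # Walk outwards in both directions until a node pixel or a cycle.
        chain = [(int(r0), int(c0))]
        visited[r0, c0] = True
        anchors: list[tuple[int, int] | None] = []
        cycle = False
        for direction in (0, 1):
            prev = chain[-1] if direction == 0 else chain[0]
            nbrs = true_neighbors(*prev)
            # at the start both neighbors are candidates; pick per direction
            if len(nbrs) != 2:  # slab pixel contract
                raise NotASkeleton(f"slab pixel {prev} has {len(nbrs)} neighbors")
            cand = nbrs[direction] if len(chain) == 1 else None
            if cand is None:
                # continue from the current end, excluding the pixel we came from
                inner = chain[-2] if direction == 0 else chain[1]
                cand = nbrs[0] if nbrs[1] == inner else nbrs[1]
            cur, came = cand, prev
            while True:
                if node_id_map[cur] >= 0:
                    anchors.append(cur)
                    break
                if cur in (chain[0], chain[-1]) and visited[cur]:
                    cycle = True
                    anchors.append(None)
                    break
                visited[cur] = True
                if direction == 0:
                    chain.append(cur)
                else:
                    chain.insert(0, cur)
                nbrs2 = true_neighbors(*cur)
                nxt = [q for q in nbrs2 if q != came]
                if len(nbrs2) != 2 or not nxt:
                    raise NotASkeleton(f"slab pixel {cur} has {len(nbrs2)} neighbors")
                came, cur = cur, nxt[0]
            if cycle:
                break
        if cycle:
            # pure slab ring, no node anywhere on it
            start = min(range(len(chain)), key=lambda i: chain[i])
            chain = chain[start:] + chain[:start]
            alpha = _path_length_px(chain, closed=True)
            emit(chain, None, None, alpha, 0.0, True, False)
            continue
        anchor_b, anchor_a = anchors  # direction 0 walked forward, 1 backward
        # canonical orientation: path runs anchor_min_side first
        path = [anchor_a, *chain, anchor_b]
        if path[-1] < path[0] or (path[-1] == path[0] and path[-2] < path[1]):
            path = path[::-1]
        na = int(node_id_map[path[0]])
        nb = int(node_id_map[path[-1]])
        alpha = _path_length_px(path)
        beta = float(np.hypot(path[0][0] - path[-1][0], path[0][1] - path[-1][1]))
        is_loop = na == nb
        endpointish = nodes[na].kind == "endpoint" or nodes[nb].kind == "endpoint"
        emit(path, na, nb, alpha, beta, is_loop, endpointish)

    # --- zero-slab branches: endpoint pixel directly adjacent to a node pixel ---
    for r, c in zip(*np.nonzero(endpoint_px)):
        nbrs = true_neighbors(int(r), int(c))
        if not nbrs:
            continue  # isolated pixel: node only
        (qr, qc) = nbrs[0]
        if not (endpoint_px[qr, qc] or junction_px[qr, qc]):
            continue  # neighbor is slab: handled by chain tracing
        if endpoint_px[qr, qc] and (qr, qc) < (int(r), int(c)):
            continue  # endpoint-endpoint pair: emit once
        path = [(int(r), int(c)), (qr, qc)]
        na, nb = int(node_id_map[path[0]]), int(node_id_map[path[1]])
        alpha = _path_length_px(path)
        emit(path, na, nb, alpha, alpha, na == nb, True)

    if validate:
        _validate_thin(P, junction_px, jl, n_j, incident_ends, node_id_map)

    return SkeletonGraph(nodes=nodes, branches=branches, pixel_size_um=px_um)


def _validate_thin(P, junction_px, jl, n_j, incident_ends, node_id_map) -> None:
    """Reject thick (never-thinned) inputs.

    A 2×2 all-true block always classifies as junction pixels; it is accepted
    only when its node cluster anchors at least one branch end (as thick
    nodes left by thinning folds and crossings do).
    """
    block = P[:-1, :-1] & P[:-1, 1:] & P[1:, :-1] & P[1:, 1:]
    if not block.any():
        return
    for r, c in zip(*np.nonzero(block)):
        corners = [(r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)]
        if not all(junction_px[p] for p in corners):
            raise NotASkeleton(f"2x2 foreground block at {(int(r), int(c))}")
        nid = int(node_id_map[corners[0]])
        if incident_ends.get(nid, 0) < 1:
            raise NotASkeleton(
                f"2x2 block in node {nid} with no incident branches"
            )
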