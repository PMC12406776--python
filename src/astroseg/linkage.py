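"""Fragment linkage: merge fragmented detections into whole cells.

Non-uniform intensity inside a cell splits the initial detection into many
fragments.  They are re-joined on a graph with one node per fragment and,
for every pair, an edge carrying the *brightest path* between them — the
8-connected pixel path that maximizes the minimum intensity along the way
(max-bottleneck / widest path) — weighted by the path's mean intensity.
The globally optimal linkage is the spanning tree of maximal total weight
(equivalently, the minimum spanning tree after brightness inversion), so
fragments are never joined through dim background when a brighter route
exists.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from .image import as_image

__all__ = [
    "LinkageTree",
    "CellMask",
    "brightest_path",
    "build_fragment_graph",
    "link_fragments",
    "assemble_cells",
]

_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _coords(obj):
    if hasattr(obj, "pixels"):
        rr, cc = obj.pixels
    else:
        rr, cc = obj
    return np.asarray(rr, dtype=np.intp), np.asarray(cc, dtype=np.intp)


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)


def brightest_path(img, a, b, envelope: int | None = 50):
    """Max-bottleneck 8-connected pixel path between two fragments.

    Returns ``(path, weight)`` where ``path`` is the list of (row, col)
    pixels from a boundary pixel of ``a`` to a boundary pixel of ``b``
    (terminals included) and ``weight`` is the mean intensity over all path
    pixels.  The path maximizes the minimum intensity en route; among
    bottleneck-optimal routes a deterministic shortest path is returned.

    The search is restricted to the bounding box of the two fragments
    dilated by ``envelope`` pixels (None searches the whole image).
    """
    im = as_image(img)
    a_r, a_c = _coords(a)
    b_r, b_c = _coords(b)
    h, w = im.shape
    if envelope is None:
        r0, r1, c0, c1 = 0, h, 0, w
    else:
        r0 = max(int(min(a_r.min(), b_r.min())) - envelope, 0)
        r1 = min(int(max(a_r.max(), b_r.max())) + envelope + 1, h)
        c0 = max(int(min(a_c.min(), b_c.min())) - envelope, 0)
        c1 = min(int(max(a_c.max(), b_c.max())) + envelope + 1, w)
    inten = im.pixels[r0:r1, c0:c1].astype(float)
    ch, cw = inten.shape
    A = np.zeros((ch, cw), dtype=bool)
    A[a_r - r0, a_c - c0] = True
    B = np.zeros((ch, cw), dtype=bool)
    B[b_r - r0, b_c - c0] = True

    seeds = _boundary(A)
    if not seeds.any():
        seeds = A
    seed_list = sorted(zip(*np.nonzero(seeds)))
    if not seed_list:
        return [], 0.0

    # phase 1: widest-path Dijkstra for the optimal bottleneck value
    best = np.full((ch, cw), -math.inf)
    heap = []
    for r, c in seed_list:
        v = inten[r, c]
        best[r, c] = v
        heapq.heappush(heap, (-v, r, c))
    bstar = None
    while heap:
        nv, r, c = heapq.heappop(heap)
        v = -nv
        if v < best[r, c]:
            continue
        if B[r, c]:
            bstar = v
            break
        for dr, dc in _OFFSETS8:
            nr, nc = r + dr, c + dc
            if 0 <= nr < ch and 0 <= nc < cw:
                nb = min(v, inten[nr, nc])
                if nb > best[nr, nc]:
                    best[nr, nc] = nb
                    heapq.heappush(heap, (-nb, nr, nc))
    if bstar is None:
        return [], 0.0

    # phase 2: deterministic BFS shortest path inside {intensity >= bstar}
    ok = inten >= bstar
    prev: dict[tuple[int, int], tuple[int, int] | None] = {}
    q: deque = deque()
    for r, c in seed_list:
        if ok[r, c] and (r, c) not in prev:
            prev[(r, c)] = None
            q.append((r, c))
    end = None
    while q:
        r, c = q.popleft()
        if B[r, c]:
            end = (r, c)
            break
        for dr, dc in _OFFSETS8:
            nr, nc = r + dr, c + dc
            if 0 <= nr < ch and 0 <= nc < cw and ok[nr, nc] and (nr, nc) not in prev:
                prev[(nr, nc)] = (r, c)
                q.append((nr, nc))
    if end is None:  # pragma: no cover - cannot happen on a connected grid
        return [], 0.0
    path = []
    cur = end
    while cur is not None:
        path.append((cur[0] + r0, cur[1] + c0))
        cur = prev[cur]
    path.reverse()
    weight = float(np.mean([im.pixels[r, c] for r, c in path]))
    return path, weight


def build_fragment_graph(img, fragments, envelope: int | None = 50) -> nx.Graph:
    """Complete weighted graph over fragments.

    One node per fragment (keyed by ``fragment.id``, carrying the fragment
    as a node attribute); one edge per unordered pair with the brightest
    path and its mean intensity as ``path`` / ``weight`` attributes.
    """
    g = nx.Graph()
    for f in fragments:
        g.add_node(f.id, fragment=f)
    frs = sorted(fragments, key=lambda f: f.id)
    for i in range(len(frs)):
        for j in range(i + 1, len(frs)):
            path, weight = brightest_path(img, frs[i], frs[j], envelope=envelope)
            g.add_edge(frs[i].id, frs[j].id, weight=weight, path=path)
    return g


@dataclass
class LinkageTree:
    """Maximum-weight spanning tree (forest) over the fragment graph."""

    nodes: list
    edges: list  # (u, v, weight, path) with u < v
    total_weight: float


def link_fragments(g: nx.Graph) -> LinkageTree:
    """Spanning tree maximizing total edge weight (Kruskal, deterministic).

    Equivalent to the minimum spanning tree under the transformed cost
    ``max_weight - w``.  Ties are broken toward lexicographically smallest
    (u, v) node-id pairs.  A disconnected graph yields a spanning forest.
    """
    nodes = sorted(g.nodes)
    edges = []
    for u, v, data in g.edges(data=True):
        uu, vv = (u, v) if u <= v else (v, u)
        edges.append((uu, vv, float(data.get("weight", 0.0)), data.get("path", [])))
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))

    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen = []
    total = 0.0
    for u, v, w, path in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v, w, path))
            total += w
    return LinkageTree(nodes=nodes, edges=chosen, total_weight=total)


@dataclass
class CellMask:
    """Union of linked fragments plus their linking-path corridors."""

    mask: np.ndarray  # boolean raster
    member_ids: list
    area: int = 0

    def __post_init__(self):
        self.area = int(self.mask.sum())

    @property
    def pixels(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.mask)

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        rr, cc = self.pixels
        return set(zip(rr.tolist(), cc.tolist()))


def assemble_cells(img, fragments, tree: LinkageTree, min_link_weight: float | None = None) -> list[CellMask]:
    """Cut dim tree links and emit one connected CellMask per component.

    Tree edges with weight below ``min_link_weight`` are removed; each
    remaining connected component becomes one mask containing its member
    fragments' pixels plus the 1-px linking-path corridors of its kept
    edges.  Default threshold: half the area-weighted mean fragment
    interior intensity.  Masks are sorted by descending area.
    """
    im = as_image(img)
    if not fragments:
        return []
    by_id = {f.id: f for f in fragments}
    if min_link_weight is None:
        total_px = sum(f.area for f in fragments)
        mean_int = sum(f.mean_intensity * f.area for f in fragments) / total_px
        min_link_weight = 0.5 * mean_int

    parent = {f.id: f.id for f in fragments}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept = [e for e in tree.edges if e[2] >= min_link_weight]
    for u, v, _w, _p in kept:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv

    groups: dict = {}
    for f in fragments:
        groups.setdefault(find(f.id), []).append(f.id)

    masks = []
    for root, ids in groups.items():
        m = np.zeros(im.shape, dtype=bool)
        for fid in ids:
            f = by_id[fid]
            m[f.rows, f.cols] = True
        idset = set(ids)
        for u, v, _w, path in kept:
            if u in idset and v in idset:
                for r, c in path:
                    m[r, c] = True
        masks.append(CellMask(mask=m, member_ids=sorted(ids)))
    masks.sort(key=lambda cm: (-cm.area, cm.member_ids))
    return masks
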