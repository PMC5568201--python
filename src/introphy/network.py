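"""Distance-based split networks and clade-complexity comparison.

A NeighborNet-style agglomeration finds a circular ordering of the taxa;
split weights are then fitted to the distance matrix by ordinary least
squares constrained non-negative (active-set NNLS) over all splits
compatible with that ordering.  The resulting weighted circular split
system is realized as a planar splits graph -- the dual of the chord
arrangement the splits induce on a disk -- in which each split of positive
weight is a class of parallel edges, tree-compatible systems reduce to
trees, and conflicting splits open up boxes.  Network complexity per clade
is summarized by node degree distributions and compared with a Poisson
regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .alignment import IUPACAlignment
from .dating import distance_matrix as _distance_matrix

__all__ = [
    "SplitSystem",
    "genetic_distances",
    "circular_ordering",
    "neighbor_net",
    "build_splits_graph",
    "degree_distribution",
    "group_degrees",
    "poisson_glm_compare",
    "write_nexus_splits",
]


class NetworkError(ValueError):
    pass


def genetic_distances(alignment: IUPACAlignment, model: str = "TN93") -> pd.DataFrame:
    """Model-corrected distances on the full concatenated alignment."""
    return _distance_matrix(alignment, model=model)


# ---------------------------------------------------------------------------
# NeighborNet agglomeration -> circular ordering


def circular_ordering(dist: pd.DataFrame) -> list[str]:
    """Circular taxon ordering by NeighborNet agglomeration.

    Clusters (paths of one or two active nodes) are joined by the
    net-divergence-adjusted selection criterion; three consecutive path
    nodes are repeatedly reduced to two surrogate nodes with the standard
    2/3-1/3 distance updates, and the recorded reductions are expanded in
    reverse at the end to yield the full circular ordering.
    """
    names = list(dist.index)
    n = len(names)
    if n <= 3:
        return names
    cap = 3 * n + 4
    d = np.zeros((cap, cap))
    d[:n, :n] = dist.to_numpy(dtype=float)
    if np.abs(d[:n, :n] - d[:n, :n].T).max() > 1e-9:
        raise NetworkError("distance matrix must be symmetric")
    next_id = n
    clusters: list[list[int]] = [[i] for i in range(n)]
    expansions: list[tuple[int, int, int, int, int]] = []  # (a, b, u, v, w)

    def cluster_dist(a: list[int], b: list[int]) -> float:
        return float(np.mean([d[x, y] for x in a for y in b]))

    while len(clusters) > 1:
        ncl = len(clusters)
        if ncl == 2:
            ia, ib = 0, 1
        else:
            dc = np.zeros((ncl, ncl))
            for i in range(ncl):
                for j in range(i + 1, ncl):
                    dc[i, j] = dc[j, i] = cluster_dist(clusters[i], clusters[j])
            rs = dc.sum(axis=1)
            q = (ncl - 2) * dc - rs[:, None] - rs[None, :]
            np.fill_diagonal(q, np.inf)
            ia, ib = divmod(int(np.argmin(q)), ncl)
            if ia > ib:
                ia, ib = ib, ia
        A, B = clusters[ia], clusters[ib]
        others = [c for k, c in enumerate(clusters) if k not in (ia, ib)]

        # second selection: members of A and B as singletons
        m = len(others) + len(A) + len(B)
        best, bx, by = np.inf, A[0], B[0]
        members = A + B
        for x in A:
            for y in B:
                rx = sum(np.mean([d[x, t] for t in c]) for c in others)
                rx += sum(d[x, z] for z in members if z != x)
                ry = sum(np.mean([d[y, t] for t in c]) for c in others)
                ry += sum(d[y, z] for z in members if z != y)
                qv = (m - 2) * d[x, y] - rx - ry
                if qv < best - 1e-12:
                    best, bx, by = qv, x, y
        # orient A so bx is last, B so by is first
        pa = A if A[-1] == bx else A[::-1]
        pb = B if B[0] == by else B[::-1]
        path = pa + pb

        while len(path) > 2:
            u, v, w = path[0], path[1], path[2]
            a_id, b_id = next_id, next_id + 1
            next_id += 2
            for t in range(next_id):
                if t in (u, v, w, a_id, b_id):
                    continue
                d[a_id, t] = d[t, a_id] = (2.0 / 3.0) * d[u, t] + (1.0 / 3.0) * d[v, t]
                d[b_id, t] = d[t, b_id] = (1.0 / 3.0) * d[v, t] + (2.0 / 3.0) * d[w, t]
            d[a_id, b_id] = d[b_id, a_id] = (
                d[u, v] + d[v, w] + d[u, w]
            ) / 3.0
            expansions.append((a_id, b_id, u, v, w))
            path = [a_id, b_id] + path[3:]

        merged = path
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(merged)

    order = list(clusters[0])
    for a_id, b_id, u, v, w in reversed(expansions):
        i = order.index(a_id)
        ln = len(order)
        if order[(i + 1) % ln] == b_id:
            order = order[:i] + [u, v, w] + order[i + 2:] if i + 1 < ln else [w] + order[1:i] + [u, v]
        elif order[(i - 1) % ln] == b_id:
            if i - 1 >= 0:
                order = order[: i - 1] + [w, v, u] + order[i + 1:]
            else:
                order = [v, u] + order[1:-1] + [w]
        else:  # pragma: no cover - adjacency is guaranteed by construction
            raise NetworkError("expansion nodes not adjacent")
        ln = len(order)
    return [names[i] for i in order]


# ---------------------------------------------------------------------------
# OLS-NNLS split weights


@dataclass
class SplitSystem:
    """Weighted circular split system.

    ``splits`` holds (side, weight) pairs where each side is a frozenset of
    taxa forming a contiguous arc of ``ordering`` that excludes the first
    taxon of the ordering.
    """

    ordering: list[str]
    splits: list[tuple[frozenset, float]]

    @property
    def n_taxa(self) -> int:
        return len(self.ordering)

    def weight_of(self, side) -> float:
        side = frozenset(side)
        comp = frozenset(self.ordering) - side
        for s, w in self.splits:
            if s == side or s == comp:
                return w
        return 0.0

    def total_weight(self) -> float:
        return sum(w for _, w in self.splits)


def _all_circular_splits(order: list[str]) -> list[frozenset]:
    n = len(order)
    out = []
    for i in range(1, n):
        for j in range(i, n):
            out.append(frozenset(order[i: j + 1]))
    return out


def neighbor_net(dist: pd.DataFrame, weight_threshold: float = 1e-9) -> SplitSystem:
    """Circular split system with non-negative OLS weights.

    The agglomerative ordering step fixes a circular ordering; split weights
    are the active-set non-negative least-squares fit of the circular split
    metric to the input distances.  Splits of weight <= ``weight_threshold``
    are dropped.
    """
    order = circular_ordering(dist)
    n = len(order)
    pos = {t: i for i, t in enumerate(order)}
    splits = _all_circular_splits(order)
    pairs = [(order[i], order[j]) for i in range(n) for j in range(i + 1, n)]
    a = np.zeros((len(pairs), len(splits)))
    for si, side in enumerate(splits):
        inside = np.zeros(n, dtype=bool)
        for t in side:
            inside[pos[t]] = True
        for pi, (u, v) in enumerate(pairs):
            if inside[pos[u]] != inside[pos[v]]:
                a[pi, si] = 1.0
    dvec = np.array([dist.loc[u, v] for u, v in pairs], dtype=float)
    w, _ = nnls(a, dvec)
    kept = [(s, float(wi)) for s, wi in zip(splits, w) if wi > weight_threshold]
    return SplitSystem(ordering=order, splits=kept)


# ---------------------------------------------------------------------------
# Splits graph (planar dual of the chord arrangement)


def _seg_intersection(p1, p2, p3, p4):
    """Proper intersection point of segments p1p2 and p3p4, or None."""
    d1 = np.asarray(p2) - np.asarray(p1)
    d2 = np.asarray(p4) - np.asarray(p3)
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-14:
        return None
    diff = np.asarray(p3) - np.asarray(p1)
    t = (diff[0] * d2[1] - diff[1] * d2[0]) / denom
    u = (diff[0] * d1[1] - diff[1] * d1[0]) / denom
    eps = 1e-9
    if eps < t < 1 - eps and eps < u < 1 - eps:
        return (p1[0] + t * d1[0], p1[1] + t * d1[1])
    return None


def build_splits_graph(system: SplitSystem) -> tuple[nx.Graph, dict[str, int]]:
    """Planar splits graph of a circular split system.

    The taxa sit on a circle; each split is a chord between the two gaps of
    its arc; the splits graph is the planar dual of the resulting chord
    arrangement.  Every split of positive weight becomes one class of
    parallel edges (edge attributes ``split`` index into
    ``system.splits`` and ``weight``), and removing a class disconnects the
    graph into the split's two sides.  Returns (graph, taxon -> node map).
    """
    order = system.ordering
    n = len(order)
    pos_of = {t: i for i, t in enumerate(order)}
    # deterministic jitter avoids concurrent chords / degenerate crossings
    jit = 0.08 * np.sin(1.7 * np.arange(n) + 0.37)
    taxon_angle = 2 * math.pi * np.arange(n) / n + jit
    gap_angle = taxon_angle + np.diff(np.append(taxon_angle, taxon_angle[0] + 2 * math.pi)) / 2.0

    # chords: split side = contiguous arc positions [a..b] -> gaps (a-1, b)
    chords = []
    for k, (side, w) in enumerate(system.splits):
        ps = sorted(pos_of[t] for t in side)
        arcs = _as_arc(ps, n)
        if arcs is None:
            raise NetworkError("split is not contiguous on the ordering")
        a, b = arcs
        chords.append((k, (a - 1) % n, b % n, w))

    # slot assignment within each gap: ccw slot order = decreasing ccw
    # distance to the other endpoint (prevents same-gap crossings)
    by_gap: dict[int, list[tuple[int, int]]] = {}
    for k, g1, g2, _ in chords:
        by_gap.setdefault(g1, []).append((k, g2))
        by_gap.setdefault(g2, []).append((k, g1))
    endpoint_angle: dict[tuple[int, int], float] = {}
    eps = 0.25 / max(n, 4) / max(len(chords), 1)
    for g, items in by_gap.items():
        items.sort(key=lambda kv: -(((kv[1] - g) % n) or n))
        for slot, (k, _) in enumerate(items):
            endpoint_angle[(k, g)] = gap_angle[g] + eps * (slot - (len(items) - 1) / 2.0)

    pts: dict[object, tuple[float, float]] = {}
    for i, t in enumerate(order):
        pts[("taxon", i)] = (math.cos(taxon_angle[i]), math.sin(taxon_angle[i]))
    chord_ends = {}
    for k, g1, g2, _ in chords:
        for g in (g1, g2):
            ang = endpoint_angle[(k, g)]
            pts[("end", k, g)] = (math.cos(ang), math.sin(ang))
        chord_ends[k] = (("end", k, g1), ("end", k, g2))

    # interior crossings
    crossings: dict[int, list[tuple[float, object]]] = {k: [] for k, *_ in chords}
    for ai in range(len(chords)):
        ka = chords[ai][0]
        pa1, pa2 = chord_ends[ka]
        for bi in range(ai + 1, len(chords)):
            kb = chords[bi][0]
            pb1, pb2 = chord_ends[kb]
            ipt = _seg_intersection(pts[pa1], pts[pa2], pts[pb1], pts[pb2])
            if ipt is not None:
                node = ("x", ka, kb)
                pts[node] = ipt
                for k, (q1, q2) in ((ka, (pa1, pa2)), (kb, (pb1, pb2))):
                    t = _param_along(pts[q1], pts[q2], ipt)
                    crossings[k].append((t, node))

    g = nx.Graph()
    for node, xy in pts.items():
        g.add_node(node, pos=xy)
    # boundary cycle
    boundary = sorted(
        (node for node in pts if node[0] in ("taxon", "end")),
        key=lambda nd: math.atan2(pts[nd][1], pts[nd][0]),
    )
    for i, nd in enumerate(boundary):
        g.add_edge(nd, boundary[(i + 1) % len(boundary)], kind="boundary")
    # chord chains
    for k, g1, g2, w in chords:
        q1, q2 = chord_ends[k]
        chain = [q1] + [nd for _, nd in sorted(crossings[k])] + [q2]
        for a_nd, b_nd in zip(chain, chain[1:]):
            g.add_edge(a_nd, b_nd, kind="chord", split=k, weight=w)

    faces = _plane_faces(g, pts)
    # dual graph over internal faces
    dual = nx.Graph()
    face_of_dir = {}
    for fi, face in enumerate(faces):
        for de in face["edges"]:
            face_of_dir[de] = fi
    internal = [fi for fi, f in enumerate(faces) if not f["outer"]]
    for fi in internal:
        dual.add_node(fi)
    for u, v, data in g.edges(data=True):
        if data.get("kind") != "chord":
            continue
        f1 = face_of_dir[(u, v)]
        f2 = face_of_dir[(v, u)]
        if f1 != f2:
            dual.add_edge(f1, f2, split=data["split"], weight=data["weight"])

    taxon_node: dict[str, int] = {}
    for i, t in enumerate(order):
        nd = ("taxon", i)
        idx = boundary.index(nd)
        nxt = boundary[(idx + 1) % len(boundary)]
        f1 = face_of_dir[(nd, nxt)]
        f2 = face_of_dir[(nxt, nd)]
        taxon_node[t] = f1 if not faces[f1]["outer"] else f2
    # relabel dual nodes to small ints for stable output
    mapping = {fi: i for i, fi in enumerate(sorted(dual.nodes()))}
    dual = nx.relabel_nodes(dual, mapping)
    taxon_node = {t: mapping[f] for t, f in taxon_node.items()}
    for t, f in taxon_node.items():
        dual.nodes[f].setdefault("taxa", []).append(t)
    return dual, taxon_node


def _as_arc(positions: list[int], n: int):
    """(first, last) of a contiguous circular arc, or None."""
    k = len(positions)
    posset = set(positions)
    for start in positions:
        if (start - 1) % n not in posset:
            if all((start + off) % n in posset for off in range(k)):
                return start, (start + k - 1) % n
            return None
    return None  # full circle (invalid split)


def _param_along(p1, p2, p) -> float:
    dx, dy = p2[0] - p1[0], p2[1] - p1[1]
    if abs(dx) >= abs(dy):
        return (p[0] - p1[0]) / dx
    return (p[1] - p1[1]) / dy


def _plane_faces(g: nx.Graph, pts: dict) -> list[dict]:
    """Faces of a straight-line plane graph via the next-clockwise-edge rule."""
    nbrs: dict[object, list[object]] = {}
    for nd in g.nodes:
        ns = list(g.neighbors(nd))
        x0, y0 = pts[nd]
        ns.sort(key=lambda m: math.atan2(pts[m][1] - y0, pts[m][0] - x0))
        nbrs[nd] = ns  # ccw order
    visited = set()
    faces = []
    for u in g.nodes:
        for v in g.neighbors(u):
            if (u, v) in visited:
                continue
            face_edges = []
            a, b = u, v
            while (a, b) not in visited:
                visited.add((a, b))
                face_edges.append((a, b))
                ring = nbrs[b]
                i = ring.index(a)
                c = ring[(i - 1) % len(ring)]  # next clockwise from a around b
                a, b = b, c
            poly = [pts[e[0]] for e in face_edges]
            area = 0.0
            for (x1, y1), (x2, y2) in zip(poly, poly[1:] + poly[:1]):
                area += x1 * y2 - x2 * y1
            faces.append({"edges": face_edges, "outer": area < 0})
    return faces


# ---------------------------------------------------------------------------
# Degrees and Poisson comparison


def degree_distribution(graph: nx.Graph) -> pd.Series:
    """Multiset of node degrees, as counts indexed by degree."""
    degs = [d for _, d in graph.degree()]
    return pd.Series(degs, dtype=int).value_counts().sort_index()


def group_degrees(
    graph: nx.Graph,
    taxon_node: dict[str, int],
    group_map: dict[str, str],
    system: SplitSystem,
) -> dict[str, list[int]]:
    """Per-group node degrees on each group's region of the joint network.

    When a split exactly separating the two groups exists, its edge class is
    removed and each component's induced subgraph supplies that group's
    degrees; otherwise nodes are assigned to the group of the nearest taxon
    node (graph distance, deterministic tie-break) and degrees are taken on
    the induced subgraphs.
    """
    groups = sorted(set(group_map.values()))
    if len(groups) != 2:
        raise NetworkError("degree comparison needs exactly two groups")
    side1 = frozenset(t for t in taxon_node if group_map[t] == groups[0])
    split_idx = None
    for k, (side, _) in enumerate(system.splits):
        if side == side1 or side == frozenset(taxon_node) - side1:
            split_idx = k
            break
    if split_idx is not None:
        pruned = nx.Graph(
            (u, v, d) for u, v, d in graph.edges(data=True) if d.get("split") != split_idx
        )
        pruned.add_nodes_from(graph.nodes)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(pruned)):
            for nd in comp:
                comp_of[nd] = ci
        assign = {nd: None for nd in graph.nodes}
        comp_group = {}
        for t, nd in taxon_node.items():
            comp_group[comp_of[nd]] = group_map[t]
        for nd in graph.nodes:
            assign[nd] = comp_group.get(comp_of[nd])
    else:
        dist_to = {
            g: nx.multi_source_dijkstra_path_length(
                graph, {taxon_node[t] for t in taxon_node if group_map[t] == g}
            )
            for g in groups
        }
        assign = {}
        for nd in graph.nodes:
            d0 = dist_to[groups[0]].get(nd, np.inf)
            d1 = dist_to[groups[1]].get(nd, np.inf)
            assign[nd] = groups[0] if d0 <= d1 else groups[1]
    out = {}
    for gname in groups:
        nodes = [nd for nd, a in assign.items() if a == gname]
        sub = graph.subgraph(nodes)
        out[gname] = sorted(d for _, d in sub.degree())
    return out


@dataclass
class DegreeComparison:
    coef: float
    se: float
    z: float
    p: float
    group_means: dict


def poisson_glm_compare(degrees_group1, degrees_group2) -> DegreeComparison:
    """Poisson regression of node degree on group membership.

    Fits log E[degree] = b0 + b1 * group (group 2 coded 1) by IRLS and
    reports the group coefficient with its SE, z-value and two-sided p.
    For this saturated two-group design b1 equals the log ratio of group
    mean degrees.
    """
    import statsmodels.api as sm

    y1 = np.asarray(degrees_group1, dtype=float)
    y2 = np.asarray(degrees_group2, dtype=float)
    if y1.size == 0 or y2.size == 0:
        raise NetworkError("both degree sets must be non-empty")
    if y1.sum() == 0 or y2.sum() == 0:
        raise NetworkError("a group with all-zero degrees has no finite coefficient")
    y = np.concatenate([y1, y2])
    x = np.column_stack(
        [np.ones(y.size), np.concatenate([np.zeros(y1.size), np.ones(y2.size)])]
    )
    fit = sm.GLM(y, x, family=sm.families.Poisson()).fit(tol=1e-10)
    coef, se = float(fit.params[1]), float(fit.bse[1])
    return DegreeComparison(
        coef=coef,
        se=se,
        z=coef / se,
        p=float(fit.pvalues[1]),
        group_means={"group1": float(y1.mean()), "group2": float(y2.mean())},
    )


# ---------------------------------------------------------------------------
# IO


def read_distance_matrix(path) -> pd.DataFrame:
    """Read a distance matrix: PHYLIP square format or tab-separated table.

    PHYLIP square files start with the taxon count on the first line,
    followed by one row per taxon (name then the full row of distances).
    """
    with open(path) as fh:
        first = fh.readline().strip()
    if first.isdigit():
        n = int(first)
        names, rows = [], []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                names.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(names) != n or any(len(r) != n for r in rows):
            raise NetworkError(f"malformed PHYLIP square matrix in {path}")
        return pd.DataFrame(rows, index=names, columns=names)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phylip_distances(dist: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dist)}\n")
        for name in dist.index:
            row = " ".join(f"{v:.8f}" for v in dist.loc[name])
            fh.write(f"{name}  {row}\n")


def write_nexus_splits(system: SplitSystem, path) -> None:
    """Write the split system as a NEXUS Splits block (SplitsTree-readable)."""
    taxa = system.ordering
    idx = {t: i + 1 for i, t in enumerate(taxa)}
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)};\nTAXLABELS\n")
        for i, t in enumerate(taxa, 1):
            fh.write(f"[{i}] '{t}'\n")
        fh.write(";\nEND;\n\nBEGIN Splits;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)} nsplits={len(system.splits)};\n")
        fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
        fh.write(f"CYCLE {' '.join(str(idx[t]) for t in taxa)};\nMATRIX\n")
        for side, w in system.splits:
            members = " ".join(str(idx[t]) for t in sorted(side, key=lambda s: idx[s]))
            fh.write(f"\t{w:.10g}\t{members},\n")
        fh.write(";\nEND;\n")


def write_edge_list(graph: nx.Graph, system: SplitSystem, path) -> None:
    rows = []
    for u, v, data in graph.edges(data=True):
        rows.append((u, v, data.get("split", -1), data.get("weight", 0.0)))
    pd.DataFrame(rows, columns=["node1", "node2", "split", "weight"]).to_csv(
        path, sep="\t", index=False
    )
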