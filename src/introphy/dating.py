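"""Per-locus gene trees, bootstrap filtering and mean-path-length dating.

Loci passing a minimum-length filter get a pairwise distance matrix
(JC or TN93 correction, with heterozygous IUPAC codes contributing half a
mismatch per allele comparison and pairwise deletion of missing data), a
neighbor-joining tree with nonparametric bootstrap supports, and -- after
rooting on the edge separating the two clades -- node ages by mean-path-
length (MPL) dating against a single root calibration.  Per-pair MRCA ages
across loci form the divergence-time histograms used to time gene flow:
a single peak at the species split is the expectation when gene flow is
contemporaneous with divergence (or absent), while introgression after
divergence adds a separate recent mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import IUPACAlignment, MISSING, _ALLELES
from .trees import Node, Tree

__all__ = [
    "DatingConfig",
    "TimingClassification",
    "filter_loci",
    "distance_matrix",
    "nj_tree",
    "root_between_groups",
    "bootstrap_support",
    "mpl_date",
    "date_gene_trees",
    "pair_divergence_times",
    "divergence_histogram",
    "classify_timing",
]


class DatingError(ValueError):
    pass


class SaturationError(DatingError):
    """Observed divergence outside the domain of the distance correction."""


@dataclass(frozen=True)
class DatingConfig:
    """Root calibration (Mya) and filter thresholds for the dating pipeline."""

    root_age: float = 9.5
    min_locus_length: int = 500
    min_mean_support: float = 50.0
    n_bootstrap: int = 100
    distance_model: str = "JC"

    def __post_init__(self) -> None:
        if self.root_age <= 0:
            raise DatingError("root_age must be > 0")


def filter_loci(loci: pd.DataFrame, min_length: int = 500) -> pd.DataFrame:
    """Keep loci with length >= min_length bp."""
    lengths = loci["end"] - loci["start"]
    return loci[lengths >= min_length].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Distances

# 256 x 4 allele-mass table per IUPAC character
_MASS = np.zeros((256, 4))
for _c in range(256):
    a1, a2 = _ALLELES[_c]
    if a1 != 255:
        _MASS[_c, a1] += 0.5
        _MASS[_c, a2] += 0.5


def _pair_site_stats(row_i: np.ndarray, row_j: np.ndarray):
    """Per-site mismatch masses split by substitution type, plus valid mask."""
    m1 = _MASS[row_i.view(np.uint8)]
    m2 = _MASS[row_j.view(np.uint8)]
    valid = (m1.sum(axis=1) > 0) & (m2.sum(axis=1) > 0)
    # expected mismatch mass per site = 1 - sum_b f1(b) f2(b)
    match = (m1 * m2).sum(axis=1)
    ag = m1[:, 0] * m2[:, 2] + m1[:, 2] * m2[:, 0]
    ct = m1[:, 1] * m2[:, 3] + m1[:, 3] * m2[:, 1]
    total = 1.0 - match
    return valid, total, ag, ct, m1, m2


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"JC correction undefined for p = {p:.4f} >= 0.75")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def _tn93_correct(p1: float, p2: float, q: float, freqs: np.ndarray) -> float:
    ga, gc, gg, gt = freqs
    gr, gy = ga + gg, gc + gt
    k1 = 2.0 * ga * gg / gr
    k2 = 2.0 * gc * gt / gy
    k3 = 2.0 * (gr * gy - ga * gg * gy / gr - gc * gt * gr / gy)
    w1 = 1.0 - p1 / k1 - q / (2.0 * gr)
    w2 = 1.0 - p2 / k2 - q / (2.0 * gy)
    w3 = 1.0 - q / (2.0 * gr * gy)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("TN93 correction undefined (saturated pair)")
    return float(-k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3))


def distance_matrix(
    alignment: IUPACAlignment,
    model: str = "JC",
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Model-corrected pairwise distances with frequency-weighted IUPAC codes.

    ``weights`` optionally resamples sites (bootstrap column counts).
    Raises :class:`SaturationError` when a pair is beyond the correction's
    domain and :class:`DatingError` when a pair has no overlapping data.
    """
    if model not in ("JC", "TN93"):
        raise DatingError(f"unknown distance model {model!r}")
    n = alignment.n_taxa
    d = np.zeros((n, n))
    rows = [alignment.matrix[i] for i in range(n)]
    if model == "TN93":
        # alignment-wide base frequencies (the conventional default)
        freqs = _MASS[alignment.matrix.view(np.uint8).ravel()].sum(axis=0)
        freqs = freqs / freqs.sum()
    for i in range(n):
        for j in range(i + 1, n):
            valid, total, ag, ct, _, _ = _pair_site_stats(rows[i], rows[j])
            w = valid.astype(float) if weights is None else weights * valid
            n_valid = w.sum()
            if n_valid == 0:
                raise DatingError(
                    f"no overlapping sites for {alignment.taxa[i]}/{alignment.taxa[j]}"
                )
            p = float((total * w).sum() / n_valid)
            if model == "JC":
                d[i, j] = d[j, i] = _jc_correct(p)
            else:
                p_ag = float((ag * w).sum() / n_valid)
                p_ct = float((ct * w).sum() / n_valid)
                q = p - p_ag - p_ct
                d[i, j] = d[j, i] = _tn93_correct(p_ag, p_ct, q, freqs)
    return pd.DataFrame(d, index=alignment.taxa, columns=alignment.taxa)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dist: pd.DataFrame) -> Tree:
    """Neighbor joining with deterministic tie-breaks.

    Negative estimated branch lengths are clamped to zero with the deficit
    moved to the adjacent branch of the same join.  The returned tree is
    unrooted, represented with a trifurcating (or, for 2 taxa, bifurcating)
    root; use :func:`root_between_groups` to place the root.
    """
    m = dist.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or np.abs(m - m.T).max() > 1e-9:
        raise DatingError("distance matrix must be symmetric")
    names = list(dist.index)
    n = len(names)
    if n < 2:
        raise DatingError("need >= 2 taxa")
    nodes = [Node(name=nm) for nm in names]
    active = list(range(n))
    d = m.copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), r)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (row_sums[i_loc] - row_sums[j_loc]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances to the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    root = Node()
    if len(active) == 3:
        i, j, k = active
        # three-point formulas
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            nodes[idx].length = max(ln, 0.0)
            root.add_child(nodes[idx])
    else:
        i, j = active
        nodes[i].length = d[i, j] / 2.0
        nodes[j].length = d[i, j] / 2.0
        root.add_child(nodes[i])
        root.add_child(nodes[j])
    return Tree(root)


def root_between_groups(tree: Tree, group_map: dict[str, str]) -> tuple[Tree, bool]:
    """Root an unrooted NJ tree on the edge separating the two groups.

    Returns (rooted tree, used_group_edge).  When no edge induces the group
    bipartition the tree is midpoint-rooted instead and the flag is False.
    """
    leaves = tree.leaf_names()
    groups = sorted({group_map[t] for t in leaves})
    target = None
    if len(groups) == 2:
        side1 = frozenset(t for t in leaves if group_map[t] == groups[0])
        target = side1

    edges = []
    for n in tree.preorder():
        for c in n.children:
            edges.append((n, c, c.length))

    chosen = None
    if target is not None:
        for parent, child, length in edges:
            below = frozenset(leaf.name for leaf in _leaves_below(child))
            if below == target or below == frozenset(leaves) - target:
                chosen = (parent, child, length)
                break
    used_group_edge = chosen is not None
    if chosen is None:
        chosen = _midpoint_edge(tree, edges)

    parent, child, length = chosen
    # balance the root on the edge: equal maximum root-to-tip heights on
    # both sides (clamped), so ultrametric input yields a clock-like tree
    h_child = _max_leaf_depth(child)
    h_parent = _max_leaf_depth_away(tree, parent, child)
    x = min(max((h_parent - h_child + length) / 2.0, 0.0), length)
    return _reroot_on_edge(tree, parent, child, x), used_group_edge


def _max_leaf_depth(node: Node) -> float:
    if node.is_leaf:
        return 0.0
    return max(c.length + _max_leaf_depth(c) for c in node.children)


def _max_leaf_depth_away(tree: Tree, start: Node, excluded: Node) -> float:
    """Longest path from ``start`` to any leaf not through ``excluded``."""
    adj: dict[Node, list[tuple[Node, float]]] = {}
    for n in tree.preorder():
        for c in n.children:
            adj.setdefault(n, []).append((c, c.length))
            adj.setdefault(c, []).append((n, c.length))
    best = 0.0
    stack = [(start, excluded, 0.0)]
    while stack:
        node, prev, acc = stack.pop()
        nbrs = [(nb, ln) for nb, ln in adj.get(node, []) if nb is not prev]
        if not nbrs:
            best = max(best, acc)
        for nb, ln in nbrs:
            stack.append((nb, node, acc + ln))
    return best


def _leaves_below(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def _midpoint_edge(tree: Tree, edges):
    """Edge containing the midpoint of the longest leaf-to-leaf path."""
    # distances from each leaf via the rooted structure
    depth: dict[Node, float] = {tree.root: 0.0}
    for n in tree.preorder():
        for c in n.children:
            depth[c] = depth[n] + c.length
    leaves = tree.leaves()
    # path length between leaves via LCA in the rooted representation
    best = (None, -1.0)
    ancestors: dict[Node, list[Node]] = {}
    for leaf in leaves:
        chain, n = [], leaf
        while n is not None:
            chain.append(n)
            n = n.parent
        ancestors[leaf] = chain
    for i, a in enumerate(leaves):
        seta = set(ancestors[a])
        for b in leaves[i + 1:]:
            lca = next(n for n in ancestors[b] if n in seta)
            plen = depth[a] + depth[b] - 2 * depth[lca]
            if plen > best[1]:
                best = ((a, b, lca), plen)
    (a, b, lca), plen = best
    half = plen / 2.0
    # walk from a up to lca, then down to b, finding where half is crossed
    path = []
    n = a
    while n is not lca:
        path.append((n.parent, n, n.length))
        n = n.parent
    down = []
    n = b
    while n is not lca:
        down.append((n.parent, n, n.length))
        n = n.parent
    path.extend(reversed(down))
    acc = 0.0
    for parent, child, length in path:
        if acc + length >= half:
            return (parent, child, length)
        acc += length
    return path[-1]


def _reroot_on_edge(tree: Tree, parent: Node, child: Node, dist_from_child: float) -> Tree:
    """Create a new root on the (parent, child) edge at the given offset."""
    adj: dict[Node, list[tuple[Node, float]]] = {}
    for n in tree.preorder():
        for c in n.children:
            adj.setdefault(n, []).append((c, c.length))
            adj.setdefault(c, []).append((n, c.length))
    new_root = Node()
    total = child.length
    adj[new_root] = [(child, dist_from_child), (parent, max(total - dist_from_child, 0.0))]
    adj[child].remove((parent, total))
    adj[child].append((new_root, dist_from_child))
    adj[parent].remove((child, total))
    adj[parent].append((new_root, max(total - dist_from_child, 0.0)))

    # rebuild rooted structure by BFS from new_root
    def build(node: Node, prev: Node | None) -> Node:
        fresh = Node(name=node.name)
        for nb, ln in adj.get(node, []):
            if nb is prev:
                continue
            sub = build(nb, node)
            sub.length = ln
            fresh.add_child(sub)
        return fresh

    rooted = build(new_root, None)
    # suppress pass-through nodes with a single child (old trifurcation root)
    def suppress(n: Node) -> None:
        for c in list(n.children):
            suppress(c)
        if len(n.children) == 1 and n.parent is not None:
            only = n.children[0]
            only.length += n.length
            gp = n.parent
            gp.children[gp.children.index(n)] = only
            only.parent = gp

    suppress(rooted)
    if len(rooted.children) == 1:
        rooted = rooted.children[0]
        rooted.parent = None
        rooted.length = 0.0
    return Tree(rooted)


# ---------------------------------------------------------------------------
# Bootstrap


def _nj_index_bipartitions(d: np.ndarray) -> set[frozenset]:
    """Internal bipartitions (canonical leaf-index sets excluding 0) of NJ(d)."""
    n = d.shape[0]
    full = frozenset(range(n))
    active = list(range(n))
    clusters = {i: frozenset((i,)) for i in range(n)}
    d = d.copy()
    bips: set[frozenset] = set()
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), r)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        new_id = d.shape[0] - 1
        side = clusters[i] | clusters[j]
        clusters[new_id] = side
        if 0 in side:
            side = full - side
        if 1 < len(side) < n - 1:
            bips.add(side)
        active = [a for a in active if a not in (i, j)] + [new_id]
    return bips


def bootstrap_support(
    alignment: IUPACAlignment,
    tree: Tree,
    n_replicates: int = 100,
    seed: int | np.random.Generator = 0,
    model: str = "JC",
) -> float:
    """Nonparametric bootstrap supports for the internal edges of ``tree``.

    Columns are resampled with replacement, the NJ tree rebuilt per
    replicate, and each internal bipartition scored as the percentage of
    replicates containing it.  Supports are written onto the tree's internal
    edges; the mean support is returned (100.0 when no internal edge
    exists).  Replicates with saturated or undefined distances count as not
    supporting any bipartition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_replicates <= 0:  # bootstrap disabled: filter passes everything
        return 100.0
    all_leaves = frozenset(tree.leaf_names())
    target = {}
    leaf_idx = {t: i for i, t in enumerate(alignment.taxa)}
    n = alignment.n_taxa
    full = frozenset(range(n))
    for node in tree.internal_edges():
        below = frozenset(leaf_idx[leaf.name] for leaf in _leaves_below(node))
        if 1 < len(below) < len(all_leaves) - 1:
            if 0 in below:
                below = full - below
            target[node] = below
    if not target:
        return 100.0

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    L = alignment.n_sites
    totals = np.empty((len(pairs), L))
    valids = np.empty((len(pairs), L))
    ags = np.empty((len(pairs), L))
    cts = np.empty((len(pairs), L))
    for pi, (i, j) in enumerate(pairs):
        valid, total, ag, ct, _, _ = _pair_site_stats(alignment.matrix[i],
                                                      alignment.matrix[j])
        valids[pi] = valid
        totals[pi] = total * valid
        ags[pi] = ag * valid
        cts[pi] = ct * valid

    w = rng.multinomial(L, np.full(L, 1.0 / L), size=n_replicates).astype(float)
    nv = w @ valids.T  # (R, n_pairs)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (w @ totals.T) / nv
        if model == "JC":
            dcorr = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * p / 3.0), np.nan)
        else:
            # TN93 per replicate, using the pooled empirical base frequencies
            freqs = _MASS[alignment.matrix.view(np.uint8).ravel()].sum(axis=0)
            freqs = freqs / freqs.sum()
            p_ag = (w @ ags.T) / nv
            p_ct = (w @ cts.T) / nv
            dcorr = np.empty_like(p)
            for r in range(n_replicates):
                for pi in range(len(pairs)):
                    try:
                        dcorr[r, pi] = _tn93_correct(
                            p_ag[r, pi], p_ct[r, pi],
                            p[r, pi] - p_ag[r, pi] - p_ct[r, pi], freqs)
                    except SaturationError:
                        dcorr[r, pi] = np.nan

    hits = {node: 0 for node in target}
    dmat = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    for r in range(n_replicates):
        row = dcorr[r]
        if not np.all(np.isfinite(row)):
            continue
        dmat[iu] = row
        dmat.T[iu] = row
        bips = _nj_index_bipartitions(dmat)
        for node, below in target.items():
            if below in bips:
                hits[node] += 1
    supports = []
    for node, h in hits.items():
        node.support = 100.0 * h / n_replicates
        supports.append(node.support)
    return float(np.mean(supports))


# ---------------------------------------------------------------------------
# MPL dating


def mpl_date(tree: Tree, root_age: float = 9.5) -> tuple[Tree, bool]:
    """Mean-path-length dating against a fixed root age.

    Each internal node's MPL is the mean path length (substitutions/site)
    to its descendant tips; ages scale MPL by root_age / MPL(root).  Child
    ages exceeding their parent's are clipped (monotonicity repair); the
    returned flag reports whether any clip was applied.  Tips are at age 0.
    """
    if root_age <= 0:
        raise DatingError("root_age must be > 0")
    dated = tree.copy()
    stats: dict[Node, tuple[float, int]] = {}
    for n in dated.postorder():
        if n.is_leaf:
            stats[n] = (0.0, 1)
            continue
        tot, cnt = 0.0, 0
        for c in n.children:
            s, k = stats[c]
            if c.length < 0:
                raise DatingError("negative branch length")
            tot += s + c.length * k
            cnt += k
        stats[n] = (tot, cnt)
    mpl_root = stats[dated.root][0] / stats[dated.root][1]
    if mpl_root <= 0:
        raise DatingError("MPL(root) = 0: cannot date a zero-length tree")
    clipped = False
    for n in dated.preorder():
        if n.is_leaf:
            n.age = 0.0
            continue
        tot, cnt = stats[n]
        age = root_age * (tot / cnt) / mpl_root
        if n.parent is not None and age > n.parent.age:
            age = n.parent.age
            clipped = True
        n.age = age
    dated.set_lengths_from_ages()
    return dated, clipped


# ---------------------------------------------------------------------------
# Per-locus pipeline and timing histograms


@dataclass
class DatedLocus:
    locus_id: str
    tree: Tree
    mean_support: float
    clipped: bool
    rooted_on_group_edge: bool


def date_gene_trees(
    alignment: IUPACAlignment,
    group_map: dict[str, str],
    config: DatingConfig = DatingConfig(),
    seed: int = 0,
) -> tuple[list[DatedLocus], pd.DataFrame]:
    """Run the locus pipeline: filter, distances, NJ, bootstrap, MPL dating.

    Returns the dated loci that pass the length and mean-support filters and
    a per-locus report (locus_id, length, status, mean_support).
    """
    if alignment.loci is None:
        raise DatingError("alignment has no locus table")
    rng = np.random.default_rng(seed)
    report, dated = [], []
    kept = filter_loci(alignment.loci, config.min_locus_length)
    kept_ids = set(kept["locus_id"])
    for _, row in alignment.loci.iterrows():
        lid = str(row["locus_id"])
        length = int(row["end"] - row["start"])
        if lid not in kept_ids:
            report.append((lid, length, "short", np.nan))
            continue
        sub = alignment.slice_sites(int(row["start"]), int(row["end"]))
        try:
            dm = distance_matrix(sub, model=config.distance_model)
            tree = nj_tree(dm)
        except SaturationError:
            report.append((lid, length, "saturated", np.nan))
            continue
        except DatingError:
            report.append((lid, length, "no_overlap", np.nan))
            continue
        mean_support = bootstrap_support(sub, tree, config.n_bootstrap, rng,
                                         model=config.distance_model)
        if not mean_support > config.min_mean_support:
            report.append((lid, length, "low_support", mean_support))
            continue
        rooted, on_group = root_between_groups(tree, group_map)
        try:
            dated_tree, clipped = mpl_date(rooted, config.root_age)
        except DatingError:
            report.append((lid, length, "undatable", mean_support))
            continue
        dated.append(DatedLocus(lid, dated_tree, mean_support, clipped, on_group))
        report.append((lid, length, "dated", mean_support))
    rep = pd.DataFrame(report, columns=["locus_id", "length", "status", "mean_support"])
    return dated, rep


def pair_divergence_times(
    dated: list[DatedLocus] | list[Tree],
    pair: tuple[str, str],
) -> np.ndarray:
    """Per-locus MRCA ages (Mya) for one taxon pair."""
    key = frozenset(pair)
    ages = []
    for item in dated:
        tree = item.tree if isinstance(item, DatedLocus) else item
        table = tree.pair_mrca_ages()
        if key in table:
            ages.append(table[key])
    if not ages:
        raise DatingError(f"pair {pair} absent from every dated tree")
    return np.asarray(ages)


def divergence_histogram(ages: np.ndarray, bin_width: float = 0.25) -> pd.DataFrame:
    """Fixed-bin-width histogram of divergence times."""
    ages = np.asarray(ages, dtype=float)
    n_bins = max(1, int(np.ceil(ages.max() / bin_width)))
    counts, edges = np.histogram(ages, bins=n_bins, range=(0.0, n_bins * bin_width))
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


@dataclass
class TimingClassification:
    mode_age: float
    recent_fraction: float
    label: str
    n_loci: int
    histogram: pd.DataFrame = field(repr=False, default=None)


def classify_timing(
    ages: np.ndarray,
    recent_cutoff_fraction: float = 0.2,
    recent_mass_threshold: float = 0.05,
    bin_width: float = 0.25,
) -> TimingClassification:
    """Label a divergence-time distribution per the single- vs extra-peak logic.

    The main mode is the midpoint of the tallest histogram bin; loci younger
    than ``recent_cutoff_fraction x mode`` count as recent.  A recent mass
    above ``recent_mass_threshold`` is labelled "recent gene flow present",
    otherwise "gene flow during divergence".
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 20:
        raise DatingError("timing classification needs >= 20 divergence times")
    hist = divergence_histogram(ages, bin_width)
    top = int(hist["count"].to_numpy().argmax())
    mode_age = float((hist["bin_start"][top] + hist["bin_end"][top]) / 2.0)
    cutoff = recent_cutoff_fraction * mode_age
    recent_fraction = float((ages < cutoff).mean())
    label = (
        "recent gene flow present"
        if recent_fraction > recent_mass_threshold
        else "gene flow during divergence"
    )
    return TimingClassification(
        mode_age=mode_age,
        recent_fraction=recent_fraction,
        label=label,
        n_loci=int(ages.size),
        histogram=hist,
    )
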