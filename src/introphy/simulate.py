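"""Multispecies-coalescent simulator with admixture pulses.

Generates per-locus gene trees under a dated species tree with per-branch
diploid effective population sizes, optional instantaneous admixture pulses
(backward in time, lineages in the destination branch are rerouted to the
source branch with probability ``f``), and evolves IUPAC-coded diploid
consensus sequences along them.  This realizes the confound the downstream
statistics disentangle: incomplete lineage sorting alone produces gene-tree
discordance with symmetric minority topologies, while a pulse biases one
minority topology and shifts divergence times.

Time is measured in generations internally; interfaces that speak years use
``generation_time`` (years per generation).  Loci are independent and free
of intra-locus recombination (exon-scale loci).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import IUPACAlignment
from .trees import Node, Tree

__all__ = [
    "Pulse",
    "LocusLayout",
    "DemographicModel",
    "SimulatedDataset",
    "JC",
    "GTR",
    "simulate_gene_trees",
    "evolve_sequences",
    "diploidize",
    "assemble_dataset",
]


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class Pulse:
    """Instantaneous admixture pulse.

    Backward in time, at ``time`` (generations before present) every lineage
    currently in branch ``dest`` moves to branch ``source`` with probability
    ``proportion``.  Forward in time this is a gene-flow event from the
    ``source`` population into the ``dest`` population contributing a
    fraction ``proportion`` of ``dest``'s ancestry.
    """

    time: float
    source: str
    dest: str
    proportion: float


@dataclass(frozen=True)
class LocusLayout:
    """Finite independent loci laid out on one concatenated coordinate axis.

    ``spacing`` bp of unsequenced gap are placed between consecutive loci so
    that fixed-width jackknife blocks can span several loci even when the
    sequenced fraction is small.
    """

    n_loci: int
    locus_length: int
    spacing: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.locus_length < 1 or self.spacing < 0:
            raise ModelError("invalid locus layout")

    @property
    def total_sites(self) -> int:
        return self.n_loci * self.locus_length

    @property
    def total_span(self) -> int:
        return self.n_loci * self.locus_length + (self.n_loci - 1) * self.spacing

    def table(self) -> pd.DataFrame:
        starts = np.arange(self.n_loci) * self.locus_length
        gstarts = np.arange(self.n_loci) * (self.locus_length + self.spacing)
        return pd.DataFrame(
            {
                "locus_id": [f"locus_{i}" for i in range(self.n_loci)],
                "start": starts,
                "end": starts + self.locus_length,
                "genomic_start": gstarts,
                "genomic_end": gstarts + self.locus_length,
            }
        )

    def coords(self) -> np.ndarray:
        off = np.repeat(
            np.arange(self.n_loci, dtype=np.int64) * (self.locus_length + self.spacing),
            self.locus_length,
        )
        return off + np.tile(np.arange(self.locus_length, dtype=np.int64), self.n_loci)


class DemographicModel:
    """Dated species tree + per-branch Ne + admixture pulses.

    Parameters
    ----------
    species_tree
        Rooted :class:`~introphy.trees.Tree` with branch lengths in
        generations (node ages are derived; the tree must be ultrametric).
        Internal nodes may carry labels so pulses can reference ancestral
        branches; unlabeled internal nodes are auto-named ``anc<k>``.
    ne
        Diploid effective population size, either a single value for every
        branch or a mapping from branch name (tip name or internal label) to
        Ne.  Branches absent from the mapping fall back to ``ne["default"]``.
    pulses
        List of :class:`Pulse`; each pulse time must lie strictly inside the
        existence interval of both named branches.
    mutation_rate
        Substitutions per site per generation.
    generation_time
        Years per generation, used only to convert reported ages to Mya.
    """

    def __init__(
        self,
        species_tree: Tree | str,
        ne: float | dict,
        pulses: list[Pulse] | None = None,
        mutation_rate: float = 1e-8,
        generation_time: float = 5.0,
    ) -> None:
        if isinstance(species_tree, str):
            species_tree = Tree.from_newick(species_tree)
        self.tree = species_tree
        self.pulses = list(pulses or [])
        self.mutation_rate = float(mutation_rate)
        self.generation_time = float(generation_time)

        self.tree.set_ages_from_lengths()
        k = 0
        for n in self.tree.preorder():
            if not n.is_leaf and not n.name:
                k += 1
                n.name = f"anc{k}"
        self.taxa = self.tree.leaf_names()
        self._by_name = {n.name: n for n in self.tree.preorder()}

        if isinstance(ne, dict):
            default = ne.get("default")
            self.ne = {}
            for n in self.tree.preorder():
                if n.name in ne:
                    self.ne[n.name] = float(ne[n.name])
                elif default is not None:
                    self.ne[n.name] = float(default)
                else:
                    raise ModelError(f"no Ne given for branch {n.name!r}")
        else:
            self.ne = {n.name: float(ne) for n in self.tree.preorder()}
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if len(self.taxa) < 3:
            raise ModelError("species tree needs >= 3 tips for triplet analyses")
        if len(set(self.taxa)) != len(self.taxa):
            raise ModelError("duplicate taxon names in species tree")
        root_age = self.tree.root.age
        for n in self.tree.preorder():
            if n.is_leaf and abs(n.age) > 1e-9 * max(root_age, 1.0):
                raise ModelError(
                    f"species tree must be ultrametric (tip {n.name!r} "
                    f"has age {n.age})"
                )
            if n.parent is not None and not n.age < n.parent.age:
                raise ModelError(
                    f"node ages must strictly decrease root->tips "
                    f"(branch {n.name!r}: {n.age} !< {n.parent.age})"
                )
        for name, v in self.ne.items():
            if not v > 0:
                raise ModelError(f"Ne must be > 0 (branch {name!r}: {v})")
        if not self.mutation_rate > 0:
            raise ModelError("mutation_rate must be > 0")
        if not self.generation_time > 0:
            raise ModelError("generation_time must be > 0")
        for p in self.pulses:
            if not 0.0 <= p.proportion <= 1.0:
                raise ModelError(f"pulse proportion must be in [0,1]: {p.proportion}")
            for which in (p.source, p.dest):
                node = self._by_name.get(which)
                if node is None:
                    raise ModelError(f"pulse references unknown branch {which!r}")
                top = math.inf if node.parent is None else node.parent.age
                if not node.age < p.time < top:
                    raise ModelError(
                        f"pulse time {p.time} outside branch {which!r} "
                        f"interval ({node.age}, {top})"
                    )

    # -- convenience -------------------------------------------------------
    def years_per_generation(self) -> float:
        return self.generation_time

    def generations(self, mya: float) -> float:
        return mya * 1e6 / self.generation_time

    def mya(self, generations: float) -> float:
        return generations * self.generation_time / 1e6

    def describe(self) -> dict:
        return {
            "taxa": self.taxa,
            "newick_generations": self.tree.to_newick(),
            "ne": self.ne,
            "pulses": [
                {"time": p.time, "source": p.source, "dest": p.dest, "f": p.proportion}
                for p in self.pulses
            ],
            "mutation_rate": self.mutation_rate,
            "generation_time": self.generation_time,
        }


# ---------------------------------------------------------------------------
# Coalescent simulation


def _simulate_locus(model: DemographicModel, rng: np.random.Generator,
                    samples_per_species: int) -> tuple[Node, int]:
    """One coalescent genealogy; returns (gene-tree root, n rerouted lineages)."""
    # events processed forward through backward time
    events: list[tuple[float, int, object]] = []
    for n in model.tree.preorder():
        if not n.is_leaf:
            events.append((n.age, 0, n))
    for p in model.pulses:
        if p.proportion > 0.0:  # f = 0 is a no-op; omitting it keeps the
            events.append((p.time, 1, p))  # RNG stream equal to the no-pulse model
    events.sort(key=lambda e: (e[0], e[1]))

    lineages: dict[str, list[Node]] = {}
    for sp in model.taxa:
        if samples_per_species == 1:
            tips = [Node(name=sp)]
        else:
            tips = [Node(name=f"{sp}/{i}") for i in range(samples_per_species)]
        for t in tips:
            t.age = 0.0
        lineages[sp] = tips

    n_rerouted = 0
    t = 0.0
    ev_i = 0
    n_total = len(model.taxa) * samples_per_species

    def coalesce_within(end: float) -> float:
        nonlocal t, n_total
        while True:
            rates = {
                b: k * (k - 1) / (4.0 * model.ne[b])
                for b, lin in lineages.items()
                if (k := len(lin)) >= 2
            }
            total = sum(rates.values())
            if total == 0.0:
                return end
            wait = rng.exponential(1.0 / total)
            if not math.isinf(end) and t + wait > end:
                return end
            t += wait
            r = rng.random() * total
            acc = 0.0
            for b, rate in rates.items():
                acc += rate
                if r <= acc:
                    branch = b
                    break
            lin = lineages[branch]
            i, j = rng.choice(len(lin), size=2, replace=False)
            i, j = (i, j) if i < j else (j, i)
            parent = Node()
            parent.age = t
            parent.add_child(lin[i])
            parent.add_child(lin[j])
            del lin[j]
            lin[i] = parent
            n_total -= 1
            if n_total == 1:
                return t

    while n_total > 1:
        end = events[ev_i][0] if ev_i < len(events) else math.inf
        coalesce_within(end)
        if n_total == 1:
            break
        t = end
        _, kind, payload = events[ev_i]
        ev_i += 1
        if kind == 0:  # speciation: child branches merge into this node's branch
            node = payload
            merged = lineages.setdefault(node.name, [])
            for c in node.children:
                merged.extend(lineages.pop(c.name, []))
        else:  # admixture pulse
            p = payload
            dest = lineages.get(p.dest, [])
            src = lineages.setdefault(p.source, [])
            kept = []
            for lin in dest:
                if rng.random() < p.proportion:
                    src.append(lin)
                    n_rerouted += 1
                else:
                    kept.append(lin)
            lineages[p.dest] = kept

    root = next(lin[0] for lin in lineages.values() if lin)
    return root, n_rerouted


def simulate_gene_trees(
    model: DemographicModel,
    n_loci: int | LocusLayout,
    seed: int,
    samples_per_species: int = 2,
) -> list[Tree]:
    """Independent coalescent gene trees, node ages in generations.

    Deterministic given ``seed``.  Each returned tree carries the number of
    pulse-rerouted lineages as ``tree.n_rerouted``.
    """
    if isinstance(n_loci, LocusLayout):
        n_loci = n_loci.n_loci
    if samples_per_species < 1:
        raise ModelError("samples_per_species must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_loci):
        root, n_re = _simulate_locus(model, rng, samples_per_species)
        tree = Tree(root)
        tree.set_lengths_from_ages()
        tree.n_rerouted = n_re
        out.append(tree)
    return out


# ---------------------------------------------------------------------------
# Sequence evolution


@dataclass(frozen=True)
class JC:
    """Jukes-Cantor model; optional gamma rate heterogeneity (shape alpha)."""

    alpha: float | None = None
    n_categories: int = 4

    @property
    def frequencies(self) -> np.ndarray:
        return np.full(4, 0.25)


@dataclass(frozen=True)
class GTR:
    """General time-reversible model with optional discrete-gamma rates.

    ``rates`` are the six exchangeabilities in the order
    (AC, AG, AT, CG, CT, GT); the rate matrix is normalized so branch
    lengths are expected substitutions per site.
    """

    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    frequencies_: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float | None = None
    n_categories: int = 4

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.frequencies_, dtype=float)

    def q_matrix(self) -> np.ndarray:
        r = np.asarray(self.rates, dtype=float)
        pi = self.frequencies
        if np.any(r <= 0) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ModelError("GTR needs positive rates and frequencies summing to 1")
        q = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for k, (i, j) in enumerate(idx):
            q[i, j] = r[k] * pi[j]
            q[j, i] = r[k] * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale


def _gamma_category_rates(alpha: float | None, k: int) -> np.ndarray:
    """Mean rates of k equal-probability discrete gamma categories."""
    if alpha is None:
        return np.ones(1)
    from scipy import stats

    edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1 / alpha)
    # category mean via the incomplete-gamma identity
    upper = stats.gamma.cdf(edges[1:], a=alpha + 1, scale=1 / alpha)
    lower = stats.gamma.cdf(edges[:-1], a=alpha + 1, scale=1 / alpha)
    return (upper - lower) * k


def evolve_sequences(
    tree: Tree,
    length: int,
    mutation_rate: float,
    seed: int | np.random.Generator,
    subst_model: JC | GTR = JC(),
) -> dict[str, np.ndarray]:
    """Simulate site-independent evolution down a dated gene tree.

    Branch lengths in expected substitutions per site are
    ``mutation_rate x branch length in generations``.  Returns one base-index
    array (values 0..3 for ACGT) per haploid tip, keyed by tip name.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cat_rates = _gamma_category_rates(subst_model.alpha, subst_model.n_categories)
    site_cat = (
        rng.integers(0, len(cat_rates), size=length)
        if len(cat_rates) > 1
        else np.zeros(length, dtype=np.int64)
    )

    pi = subst_model.frequencies
    root_state = rng.choice(4, size=length, p=pi)

    use_gtr = isinstance(subst_model, GTR)
    if use_gtr:
        q = subst_model.q_matrix()
        lam, u = np.linalg.eig(q)
        uinv = np.linalg.inv(u)

    states: dict[int, np.ndarray] = {id(tree.root): root_state}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            if node.is_leaf:
                out[node.name] = root_state
            continue
        parent_state = states[id(node.parent)]
        d = mutation_rate * node.length
        if d < 0:
            raise ModelError("negative branch length")
        child = parent_state.copy()
        for ci, r in enumerate(cat_rates):
            mask = site_cat == ci
            n_sites = int(mask.sum())
            if n_sites == 0:
                continue
            if use_gtr:
                p = np.real(u @ np.diag(np.exp(lam * d * r)) @ uinv)
                p = np.clip(p, 0, None)
                p /= p.sum(axis=1, keepdims=True)
                cum = np.cumsum(p, axis=1)
                draws = rng.random(n_sites)
                ps = parent_state[mask]
                child[mask] = (draws[:, None] > cum[ps]).sum(axis=1)
            else:
                p_diff = 0.75 * (1.0 - np.exp(-4.0 * d * r / 3.0))
                hit = rng.random(n_sites) < p_diff
                n_hit = int(hit.sum())
                if n_hit:
                    idx = np.nonzero(mask)[0][hit]
                    child[idx] = (child[idx] + 1 + rng.integers(0, 3, size=n_hit)) % 4
        states[id(node)] = child
        if node.is_leaf:
            out[node.name] = child
    return out


# ---------------------------------------------------------------------------
# Diploidization

_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")
_IUPAC_PAIR = np.empty((4, 4), dtype="S1")
for _i, _a in enumerate("ACGT"):
    for _j, _b in enumerate("ACGT"):
        if _i == _j:
            _IUPAC_PAIR[_i, _j] = _a.encode()
        else:
            from .alignment import HET_FOR_PAIR as _HFP

            _IUPAC_PAIR[_i, _j] = _HFP[frozenset((_a, _b))].encode()


def diploidize(hap1: np.ndarray, hap2: np.ndarray) -> np.ndarray:
    """Collapse two haplotypes (base indices 0-3) into one IUPAC sequence.

    Equal bases pass through; differing bases become the two-base ambiguity
    code, e.g. (A, G) -> R.
    """
    if hap1.shape != hap2.shape:
        raise ModelError("haplotypes must have equal length")
    return _IUPAC_PAIR[hap1, hap2]


# ---------------------------------------------------------------------------
# Dataset assembly


@dataclass
class SimulatedDataset:
    alignment: IUPACAlignment
    true_gene_trees: list[Tree]
    provenance: dict = field(default_factory=dict)


def assemble_dataset(
    model: DemographicModel,
    layout: LocusLayout,
    seed: int,
    subst_model: JC | GTR = JC(),
    samples_per_species: int = 2,
) -> SimulatedDataset:
    """Simulate gene trees and one IUPAC consensus sequence per species.

    The alignment concatenates all loci (coordinates follow ``layout``);
    true gene trees (ages in generations) are retained for oracle checks.
    """
    if samples_per_species not in (1, 2):
        raise ModelError("assemble_dataset supports 1 or 2 samples per species")
    rng = np.random.default_rng(seed)
    tree_seed, seq_seed = rng.integers(0, 2**31 - 1, size=2)
    trees = simulate_gene_trees(model, layout.n_loci, int(tree_seed),
                                samples_per_species=samples_per_species)
    seq_rng = np.random.default_rng(int(seq_seed))

    n_sp = len(model.taxa)
    matrix = np.empty((n_sp, layout.total_sites), dtype="S1")
    for li, tree in enumerate(trees):
        haps = evolve_sequences(tree, layout.locus_length, model.mutation_rate,
                                seq_rng, subst_model)
        sl = slice(li * layout.locus_length, (li + 1) * layout.locus_length)
        for si, sp in enumerate(model.taxa):
            if samples_per_species == 1:
                matrix[si, sl] = _BASE_BYTES[haps[sp]]
            else:
                matrix[si, sl] = diploidize(haps[f"{sp}/0"], haps[f"{sp}/1"])

    loci = layout.table()
    aln = IUPACAlignment(
        taxa=list(model.taxa),
        matrix=matrix,
        loci=loci[["locus_id", "start", "end"]].assign(
            genomic_start=loci["genomic_start"]
        ),
        coords=layout.coords(),
        total_length=layout.total_span,
    )
    return SimulatedDataset(
        alignment=aln,
        true_gene_trees=trees,
        provenance={
            "model": model.describe(),
            "seed": int(seed),
            "layout": {
                "n_loci": layout.n_loci,
                "locus_length": layout.locus_length,
                "spacing": layout.spacing,
            },
            "samples_per_species": samples_per_species,
            "subst_model": type(subst_model).__name__,
        },
    )
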