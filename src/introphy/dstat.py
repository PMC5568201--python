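"""ABBA-BABA D-statistics with block-jackknife significance.

For an ordered quartet (P1, P2, P3, O) with P1 and P2 sisters, biallelic
sites where P2 and P3 share the derived allele (ABBA) and sites where P1
and P3 share it (BABA) are equally frequent under incomplete lineage
sorting alone; an excess of one class indicates asymmetric gene flow
involving P3.  With per-taxon derived-allele frequencies p in {0, 0.5, 1}
(diploid IUPAC consensus input) the site weights are

    C_ABBA(i) = (1 - p1) * p2 * p3        C_BABA(i) = p1 * (1 - p2) * p3

and D = (sum C_ABBA - sum C_BABA) / (sum C_ABBA + sum C_BABA).

Standard errors come from delete-one jackknife over contiguous genomic
blocks (default 50 kb); blocks without informative sites are dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import (
    BlockPartition,
    IUPACAlignment,
    check_group_map,
    consensus_sequence,
    partition_blocks,
    polarize_triplet,
)

__all__ = [
    "TripletSpec",
    "SitePatternCounts",
    "TripletResult",
    "count_patterns",
    "compute_d",
    "jackknife_se",
    "jackknife_d",
    "enumerate_triplets",
    "compute_triplet",
    "run_dstat",
    "significant_triplets",
    "compare_groups",
]


class DStatError(ValueError):
    pass


@dataclass(frozen=True)
class TripletSpec:
    p1: str
    p2: str
    p3: str
    outgroup: tuple[str, ...]

    def __post_init__(self) -> None:
        trip = {self.p1, self.p2, self.p3}
        if len(trip) != 3:
            raise DStatError("P1, P2, P3 must be distinct")
        if trip & set(self.outgroup):
            raise DStatError("outgroup overlaps the triplet")


@dataclass
class SitePatternCounts:
    """Totals and per-block sub-sums of the ABBA/BABA site weights."""

    sum_abba: float
    sum_baba: float
    n_informative_sites: int
    block_abba: np.ndarray
    block_baba: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.block_abba.sum(), self.sum_abba):
            raise DStatError("block ABBA sums do not add to total")
        if not np.isclose(self.block_baba.sum(), self.sum_baba):
            raise DStatError("block BABA sums do not add to total")


@dataclass
class TripletResult:
    spec: TripletSpec
    d: float
    se: float
    z: float
    p: float
    n_blocks_used: int
    counts: SitePatternCounts
    skipped_sites: dict | None = None  # tallies by polarization skip reason


def count_patterns(
    p: np.ndarray,
    block_index: np.ndarray,
    n_blocks: int,
) -> SitePatternCounts:
    """Accumulate frequency-weighted ABBA/BABA sums per jackknife block.

    ``p`` is the (3, n_sites) derived-frequency array of a polarized
    triplet; sites with zero weight in both classes are uninformative.
    """
    p1, p2, p3 = p
    c_abba = (1.0 - p1) * p2 * p3
    c_baba = p1 * (1.0 - p2) * p3
    informative = (c_abba > 0) | (c_baba > 0)
    block_abba = np.bincount(block_index, weights=c_abba, minlength=n_blocks)
    block_baba = np.bincount(block_index, weights=c_baba, minlength=n_blocks)
    return SitePatternCounts(
        sum_abba=float(c_abba.sum()),
        sum_baba=float(c_baba.sum()),
        n_informative_sites=int(informative.sum()),
        block_abba=block_abba,
        block_baba=block_baba,
    )


def compute_d(counts: SitePatternCounts) -> float:
    denom = counts.sum_abba + counts.sum_baba
    if denom <= 0:
        raise DStatError("no informative sites")
    return (counts.sum_abba - counts.sum_baba) / denom


def jackknife_se(loo_estimates: np.ndarray) -> float:
    """Delete-one jackknife SE from the m leave-one-out estimates."""
    loo = np.asarray(loo_estimates, dtype=float)
    m = loo.size
    if m < 2:
        raise DStatError("jackknife needs >= 2 usable blocks")
    return float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))


def jackknife_d(counts: SitePatternCounts) -> tuple[float, float, float]:
    """(SE, Z, two-sided p) for D by delete-one-block jackknife.

    Blocks with no informative weight are dropped; Z = D / SE against a
    standard normal.  A degenerate SE of zero with non-zero D yields
    Z = +-inf and p = 0 (flagged by the caller via n_blocks_used).
    """
    d_full = compute_d(counts)
    usable = (counts.block_abba + counts.block_baba) > 0
    if usable.sum() < 2:
        raise DStatError("jackknife needs >= 2 blocks with informative sites")
    a = counts.block_abba[usable]
    b = counts.block_baba[usable]
    ta, tb = counts.sum_abba, counts.sum_baba
    loo = (ta - a - (tb - b)) / (ta - a + tb - b)
    se = jackknife_se(loo)
    if se == 0.0:
        z = 0.0 if d_full == 0.0 else np.sign(d_full) * np.inf
        p = 1.0 if d_full == 0.0 else 0.0
    else:
        z = d_full / se
        p = 2.0 * stats.norm.sf(abs(z))
    return se, z, p


def enumerate_triplets(group_map: dict[str, str], group: str) -> list[TripletSpec]:
    """All (P1, P2, P3) from one group, outgroup = all taxa of the others.

    P1 < P2 lexicographically (canonical orientation); every third taxon of
    the group takes the P3 slot, giving C(k,2) * (k-2) specs for k taxa.
    """
    members = sorted(t for t, g in group_map.items() if g == group)
    others = tuple(sorted(t for t, g in group_map.items() if g != group))
    if len(members) < 3:
        raise DStatError(f"group {group!r} has fewer than 3 taxa")
    if not others:
        raise DStatError("no outgroup taxa outside the focal group")
    specs = []
    for p1, p2 in itertools.combinations(members, 2):
        for p3 in members:
            if p3 not in (p1, p2):
                specs.append(TripletSpec(p1, p2, p3, others))
    return specs


def compute_triplet(
    alignment: IUPACAlignment,
    spec: TripletSpec,
    blocks: BlockPartition | None = None,
    outgroup_consensus: str | None = None,
) -> TripletResult:
    if blocks is None:
        blocks = partition_blocks(alignment)
    if outgroup_consensus is None:
        outgroup_consensus = consensus_sequence(alignment, list(spec.outgroup))
    pol = polarize_triplet(alignment, (spec.p1, spec.p2, spec.p3), outgroup_consensus)
    block_index = blocks.block_of(alignment.coords[pol.site_index])
    counts = count_patterns(pol.p, block_index, blocks.n_blocks)
    d = compute_d(counts)
    se, z, p = jackknife_d(counts)
    usable = int(((counts.block_abba + counts.block_baba) > 0).sum())
    return TripletResult(spec=spec, d=d, se=se, z=z, p=p,
                         n_blocks_used=usable, counts=counts,
                         skipped_sites=dict(pol.skip_counts))


def run_dstat(
    alignment: IUPACAlignment,
    group_map: dict[str, str],
    block_size: int = 50_000,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """D-statistics for all within-group triplets against the other group.

    Returns one row per triplet with columns
    ``group, P1, P2, P3, nABBA, nBABA, n_sites, D, SE, Z, p, n_blocks``.
    Triplets without informative sites are reported with NaN statistics.
    Aggregate skipped-site tallies by reason are attached as
    ``result.attrs["skipped_sites"]``.
    """
    check_group_map(group_map, alignment.taxa)
    blocks = partition_blocks(alignment, block_size)
    if groups is None:
        groups = sorted(set(group_map.values()))
    skipped_total: dict[str, int] = {}
    rows = []
    for g in groups:
        members = [t for t, gg in group_map.items() if gg == g]
        if len(members) < 3:
            continue
        outgroup = sorted(t for t, gg in group_map.items() if gg != g)
        cons = consensus_sequence(alignment, outgroup)
        for spec in enumerate_triplets(group_map, g):
            try:
                res = compute_triplet(alignment, spec, blocks, cons)
                for k, v in (res.skipped_sites or {}).items():
                    skipped_total[k] = skipped_total.get(k, 0) + v
                rows.append(
                    dict(group=g, P1=spec.p1, P2=spec.p2, P3=spec.p3,
                         nABBA=res.counts.sum_abba, nBABA=res.counts.sum_baba,
                         n_sites=res.counts.n_informative_sites,
                         D=res.d, SE=res.se, Z=res.z, p=res.p,
                         n_blocks=res.n_blocks_used)
                )
            except DStatError:
                rows.append(
                    dict(group=g, P1=spec.p1, P2=spec.p2, P3=spec.p3,
                         nABBA=0.0, nBABA=0.0, n_sites=0,
                         D=np.nan, SE=np.nan, Z=np.nan, p=np.nan, n_blocks=0)
                )
    out = pd.DataFrame(rows)
    out.attrs["skipped_sites"] = skipped_total
    return out


def significant_triplets(
    results: pd.DataFrame,
    z_threshold: float = 3.0,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Rows with |Z| above threshold and p below threshold.

    Each retained row is reported in the orientation that makes D positive
    (swapping P1 and P2 flips the signs of D and Z exactly), so gene flow is
    read as acting between the reported P2 and P3.
    """
    kept = results[(results["Z"].abs() > z_threshold) & (results["p"] < p_threshold)]
    kept = kept.copy()
    flip = kept["D"] < 0
    kept.loc[flip, ["P1", "P2"]] = kept.loc[flip, ["P2", "P1"]].to_numpy()
    if {"nABBA", "nBABA"}.issubset(kept.columns):
        kept.loc[flip, ["nABBA", "nBABA"]] = kept.loc[
            flip, ["nBABA", "nABBA"]].to_numpy()
    kept.loc[flip, "D"] = -kept.loc[flip, "D"]
    kept.loc[flip, "Z"] = -kept.loc[flip, "Z"]
    return kept.sort_values(["group", "P1", "P2", "P3"]).reset_index(drop=True)


@dataclass
class GroupComparison:
    w: float
    p: float
    n1: int
    n2: int


def compare_groups(d_group1, d_group2) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two sets of D values.

    W is the U statistic of the first group (the convention R's wilcox.test
    reports).  Small samples without ties use the exact null distribution;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(d_group1, dtype=float)
    y = np.asarray(d_group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DStatError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 200 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(w=float(res.statistic), p=float(res.pvalue),
                           n1=int(x.size), n2=int(y.size))
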