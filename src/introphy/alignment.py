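"""IUPAC-coded alignments, consensus sequences, site polarization and blocks.

The genomic input to the downstream analyses is one diploid consensus
sequence per taxon, with heterozygous sites encoded as two-base IUPAC
ambiguity codes (e.g. ``R`` for A/G).  This module gives those codes a
deterministic frequency semantics -- a heterozygous code contributes 0.5
allele mass to each of its two bases -- and builds the derived-allele
frequencies that feed the D-statistic, by polarizing sites against the
consensus of an outgroup clade.

Coordinates are 0-based half-open everywhere.  Gaps (``-``) and ``N`` are
missing data, never alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
#: two-base IUPAC ambiguity codes (unordered base pairs)
IUPAC_HET = {
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
}
HET_FOR_PAIR = {frozenset(v): k for k, v in IUPAC_HET.items()}
MISSING = "N-"
ALPHABET = set(BASES) | set(IUPAC_HET) | set(MISSING)

_BASE_IDX = {b: i for i, b in enumerate(BASES)}

# Per-character allele pair, encoded as small ints; 255 marks missing.
_ALLELES = np.full((256, 2), 255, dtype=np.uint8)
for _b, _i in _BASE_IDX.items():
    _ALLELES[ord(_b)] = (_i, _i)
for _c, _pair in IUPAC_HET.items():
    _ALLELES[ord(_c)] = (_BASE_IDX[_pair[0]], _BASE_IDX[_pair[1]])


class AlignmentError(ValueError):
    pass


@dataclass
class IUPACAlignment:
    """Taxa x sites matrix over {A,C,G,T, two-base IUPAC codes, N, -}.

    ``loci`` is a DataFrame with columns ``locus_id, start, end`` in
    alignment coordinates (half-open, sorted, non-overlapping).  ``coords``
    optionally maps each alignment column to a genomic coordinate on a
    single concatenated coordinate system, so that fixed-width jackknife
    blocks remain meaningful when loci are spaced out; by default it is the
    identity.
    """

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_sites) of single-byte characters ('S1')
    loci: pd.DataFrame | None = None
    coords: np.ndarray | None = None
    total_length: int | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise AlignmentError("matrix shape does not match taxon list")
        self.matrix = np.char.upper(self.matrix.astype("S1"))
        bad = set(np.unique(self.matrix).astype(str)) - ALPHABET
        if bad:
            raise AlignmentError(f"illegal characters in alignment: {sorted(bad)}")
        if self.coords is None:
            self.coords = np.arange(self.n_sites, dtype=np.int64)
        if self.total_length is None:
            self.total_length = int(self.coords[-1]) + 1 if self.n_sites else 0
        if self.loci is not None:
            _validate_loci(self.loci, self.n_sites)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return self.row(taxon).tobytes().decode()

    def allele_codes(self, taxon: str) -> np.ndarray:
        """(2, n_sites) uint8 array of allele indices into ACGT; 255 = missing."""
        return _ALLELES[self.row(taxon).view(np.uint8)].T

    def slice_sites(self, start: int, end: int) -> "IUPACAlignment":
        return IUPACAlignment(
            taxa=list(self.taxa),
            matrix=self.matrix[:, start:end].copy(),
            coords=self.coords[start:end].copy(),
            total_length=self.total_length,
        )


def _validate_loci(loci: pd.DataFrame, n_sites: int) -> None:
    required = {"locus_id", "start", "end"}
    if not required.issubset(loci.columns):
        raise AlignmentError(f"locus table needs columns {sorted(required)}")
    starts = loci["start"].to_numpy()
    ends = loci["end"].to_numpy()
    if np.any(starts >= ends):
        raise AlignmentError("empty or inverted locus interval")
    if np.any(starts[1:] < ends[:-1]):
        raise AlignmentError("locus intervals overlap or are unsorted")
    if starts.size and (starts[0] < 0 or ends[-1] > n_sites):
        raise AlignmentError("locus interval outside alignment")


# ---------------------------------------------------------------------------
# FASTA / TSV IO


def read_fasta(path) -> IUPACAlignment:
    """Read an aligned FASTA file (equal-length records, IUPAC codes)."""
    taxa, rows = [], []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        taxa.append(rec.id)
        rows.append(np.frombuffer(seq.encode(), dtype="S1"))
    if not taxa:
        raise AlignmentError(f"no FASTA records in {path}")
    return IUPACAlignment(taxa=taxa, matrix=np.vstack(rows))


def write_fasta(alignment: IUPACAlignment, path) -> None:
    records = [
        SeqRecord(Seq(alignment.sequence(t)), id=t, description="")
        for t in alignment.taxa
    ]
    SeqIO.write(records, str(path), "fasta")


def read_locus_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"locus_id": str})


def read_group_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"taxon", "group"}.issubset(df.columns):
        raise AlignmentError("group map needs columns taxon, group")
    return dict(zip(df["taxon"], df["group"]))


def check_group_map(group_map: dict[str, str], taxa: list[str]) -> None:
    missing = [t for t in taxa if t not in group_map]
    if missing:
        raise AlignmentError(f"taxa missing from group map: {missing}")


# ---------------------------------------------------------------------------
# Frequencies and consensus


def base_frequencies(alignment: IUPACAlignment, taxon: str, site: int):
    """Allele frequencies at one site: base -> frequency, or None if missing."""
    c = alignment.row(taxon)[site].decode()
    if c in MISSING:
        return None
    if c in IUPAC_HET:
        b1, b2 = IUPAC_HET[c]
        return {b1: 0.5, b2: 0.5}
    return {c: 1.0}


def allele_mass(alignment: IUPACAlignment, taxa_subset: list[str]) -> np.ndarray:
    """(4, n_sites) summed allele mass over ``taxa_subset`` (missing excluded)."""
    mass = np.zeros((4, alignment.n_sites))
    for t in taxa_subset:
        codes = alignment.allele_codes(t)
        for row in codes:  # two allele rows per taxon, 0.5 mass each
            ok = row != 255
            np.add.at(mass, (row[ok], np.nonzero(ok)[0]), 0.5)
    return mass


def consensus_sequence(alignment: IUPACAlignment, taxa_subset: list[str]) -> str:
    """Majority-rule consensus with IUPAC tie-breaking.

    Per site the allele mass of each base is summed over the subset (missing
    excluded).  A strict-majority base wins; an exact tie between the two top
    bases yields their two-base IUPAC code; a tie among more than two bases,
    or an all-missing column, yields ``N``.
    """
    if not taxa_subset:
        raise AlignmentError("consensus of an empty taxon subset")
    mass = allele_mass(alignment, taxa_subset)
    out = np.full(alignment.n_sites, b"N", dtype="S1")
    top = mass.max(axis=0)
    tol = 1e-9
    n_top = (mass >= top[None, :] - tol).sum(axis=0)
    covered = top > tol
    # strict majority
    single = covered & (n_top == 1)
    out[single] = np.frombuffer(BASES.encode(), dtype="S1")[mass.argmax(axis=0)][single]
    # exact two-way tie -> ambiguity code
    pair_sites = np.nonzero(covered & (n_top == 2))[0]
    for s in pair_sites:
        b1, b2 = np.nonzero(mass[:, s] >= top[s] - tol)[0]
        out[s] = HET_FOR_PAIR[frozenset((BASES[b1], BASES[b2]))].encode()
    return out.tobytes().decode()


# ---------------------------------------------------------------------------
# Polarization


@dataclass
class PolarizedSites:
    """Derived-allele frequencies for a (P1, P2, P3) triplet.

    Arrays are restricted to the retained sites; ``site_index`` gives their
    alignment column, ``skip_counts`` tallies discarded sites by rule.
    """

    site_index: np.ndarray
    ancestral: np.ndarray  # base characters ('S1')
    p: np.ndarray  # (3, n_kept) derived frequencies in {0, 0.5, 1}
    skip_counts: dict[str, int] = field(default_factory=dict)


def polarize_triplet(
    alignment: IUPACAlignment,
    ingroup: tuple[str, str, str],
    outgroup_consensus: str | np.ndarray,
) -> PolarizedSites:
    """Polarize all sites for one triplet against an outgroup consensus.

    A site is kept only when (a) the outgroup consensus base is an
    unambiguous A/C/G/T (it defines the ancestral state), (b) exactly two
    bases have frequency support across the three ingroup taxa plus the
    ancestral base, and (c) no ingroup taxon is missing.  The derived
    frequency of each ingroup taxon is its allele mass on the non-ancestral
    base, hence in {0, 0.5, 1}.
    """
    cons = np.asarray(
        np.frombuffer(outgroup_consensus.encode(), dtype="S1")
        if isinstance(outgroup_consensus, str)
        else outgroup_consensus
    )
    if cons.shape[0] != alignment.n_sites:
        raise AlignmentError("outgroup consensus length mismatch")
    anc_idx = np.full(alignment.n_sites, 255, dtype=np.uint8)
    for b, i in _BASE_IDX.items():
        anc_idx[cons == b.encode()] = i
    anc_ok = anc_idx != 255

    codes = np.stack([alignment.allele_codes(t) for t in ingroup])  # (3,2,L)
    missing = (codes == 255).any(axis=(0, 1))

    present = np.zeros((4, alignment.n_sites), dtype=bool)
    for i in range(4):
        present[i] = (codes == i).any(axis=(0, 1))
    ok_anc = anc_ok
    safe_anc = np.where(ok_anc, anc_idx, 0)
    present_with_anc = present.copy()
    present_with_anc[safe_anc, np.arange(alignment.n_sites)] |= ok_anc
    n_present = present_with_anc.sum(axis=0)

    biallelic = n_present == 2
    keep = ok_anc & biallelic & ~missing

    # derived base: the present base that is not ancestral
    not_anc = present_with_anc.copy()
    not_anc[safe_anc, np.arange(alignment.n_sites)] = False
    derived = not_anc.argmax(axis=0).astype(np.uint8)
    # informative only if some ingroup taxon actually carries the derived base
    keep &= present[derived, np.arange(alignment.n_sites)]

    idx = np.nonzero(keep)[0]
    p = 0.5 * (codes[:, 0, idx] == derived[idx]) + 0.5 * (codes[:, 1, idx] == derived[idx])

    n = alignment.n_sites
    skip_counts = {
        "ambiguous_ancestor": int((~ok_anc).sum()),
        "missing_ingroup": int((ok_anc & missing).sum()),
        "not_biallelic": int((ok_anc & ~missing & ~biallelic).sum()),
        "no_derived_in_ingroup": int(n - (~ok_anc).sum()
                                     - (ok_anc & missing).sum()
                                     - (ok_anc & ~missing & ~biallelic).sum()
                                     - idx.size),
    }
    return PolarizedSites(
        site_index=idx,
        ancestral=cons[idx],
        p=p.astype(float),
        skip_counts=skip_counts,
    )


def polarize_site(
    alignment: IUPACAlignment,
    site: int,
    ingroup: tuple[str, str, str],
    outgroup_consensus: str,
):
    """Single-site convenience wrapper; returns (ancestral, (p1,p2,p3)) or None."""
    sub = polarize_triplet(alignment, ingroup, outgroup_consensus)
    pos = np.searchsorted(sub.site_index, site)
    if pos >= sub.site_index.size or sub.site_index[pos] != site:
        return None
    return sub.ancestral[pos].decode(), tuple(sub.p[:, pos])


# ---------------------------------------------------------------------------
# Jackknife blocks


@dataclass
class BlockPartition:
    """Contiguous fixed-width genomic blocks covering [0, total_length)."""

    block_size: int
    total_length: int

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise AlignmentError("block_size must be >= 1")
        if self.total_length < 0:
            raise AlignmentError("total_length must be >= 0")

    @property
    def n_blocks(self) -> int:
        return max(1, math.ceil(self.total_length / self.block_size))

    def block_of(self, coord) -> np.ndarray:
        return np.asarray(coord) // self.block_size

    def boundaries(self) -> list[tuple[int, int]]:
        return [
            (b * self.block_size, min((b + 1) * self.block_size, self.total_length))
            for b in range(self.n_blocks)
        ]

    def to_bed(self, path, chrom: str = "concat") -> None:
        with open(path, "w") as fh:
            for i, (s, e) in enumerate(self.boundaries()):
                fh.write(f"{chrom}\t{s}\t{e}\tblock_{i}\n")


def partition_blocks(alignment: IUPACAlignment, block_size: int = 50_000) -> BlockPartition:
    return BlockPartition(block_size=block_size, total_length=alignment.total_length)
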