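# Methods

`introphy` implements a genome-scale workflow for separating introgression
from incomplete lineage sorting (ILS) in a clade of closely related
species, of the kind used for radiations such as the true geese: triplet
ABBA-BABA D-statistics with block-jackknife significance, per-locus gene
trees dated against a fixed root calibration to time gene flow, and a
distance-based split network whose per-clade complexity is compared by
Poisson regression.  A multispecies-coalescent simulator with admixture
pulses provides ground truth for every stage.

## Input model: diploid IUPAC consensus genomes

The expected input is one consensus sequence per taxon produced by diploid
variant calling, with heterozygous sites written as two-base IUPAC codes
(`R` = A/G etc.).  All statistics give these codes a deterministic
frequency semantics: a heterozygous code contributes allele mass 0.5 to
each of its bases, so per-taxon derived-allele frequencies take values in
{0, 0.5, 1}.  Random resolution of heterozygotes would make every
downstream number seed-dependent; the frequency form of the D-statistic
makes it exact instead.  `N` and `-` are missing data, never alleles.
Coordinates are 0-based, half-open throughout.

## Site polarization and the consensus outgroup

For a triplet (P1, P2, P3) drawn from one clade, the other clade serves as
the outgroup through its majority-rule consensus (exact two-way ties
become IUPAC codes and are subsequently excluded as ambiguous ancestors;
ties among more than two bases become `N`).  A site enters the analysis
only when (a) the outgroup consensus base is an unambiguous A/C/G/T — it
defines the ancestral state; (b) exactly two bases occur across the three
ingroup taxa plus that ancestral base (the biallelic requirement; the
outgroup's minority alleles are deliberately not consulted, since the
outgroup enters the published design only via its consensus); and
(c) no ingroup member of the triplet is missing.  Skipped sites are
tallied by reason.

## D-statistic and block jackknife

With derived frequencies (p1, p2, p3) the site weights are
C_ABBA = (1-p1)·p2·p3 and C_BABA = p1·(1-p2)·p3, and

    D = (Σ C_ABBA − Σ C_BABA) / (Σ C_ABBA + Σ C_BABA).

Under ILS alone with P1, P2 true sisters, E[D] = 0; gene flow between P3
and P2 drives D positive, between P3 and P1 negative.  Swapping P1 and P2
flips the sign exactly, so triplets are enumerated with P1 < P2
lexicographically and significant rows are reported re-oriented so D > 0
(gene flow read between the reported P2 and P3).

Significance uses a delete-one block jackknife over contiguous 50-kb
genomic blocks (configurable): SE² = ((m−1)/m)·Σ(D₍₋ⱼ₎ − D̄)², Z = D/SE,
two-sided normal p.  Blocks with zero informative weight are dropped from
the jackknife — deleting an empty block is a no-op that would deflate the
SE.  Default significance is |Z| > 3 and p < 1e-4; a stricter Z > 4
preset is available, since both thresholds appear in published practice.
The Mann-Whitney comparison of two clades' D distributions reports the
first group's U (the convention R's `wilcox.test` calls W), exact for
small tie-free samples and normal-approximated with tie correction
otherwise.

One caution established by the simulator: only triplets whose (P1, P2)
are true sisters have a null D of zero.  Misoriented triplets of an
asymmetric triple carry genuine species-tree signal and are "significant"
by construction (|Z| in the tens); on real data, where the tree is not
known a priori, the all-triplets table necessarily mixes both kinds.
The null-calibration experiment therefore scores the correctly oriented
configuration.

## Gene trees and mean-path-length dating

Loci of at least 500 bp are analysed separately: model-corrected distances
(JC or TN93 closed forms; heterozygous codes contribute 0.5 mismatch mass
per allele comparison; pairwise deletion of missing data; saturated pairs
reject the locus), neighbor joining with deterministic tie-breaks and
negative-branch clamping (the deficit moves to the adjacent branch), and
nonparametric bootstrap (default 100 column-resampling replicates).  Loci
are kept when the mean internal-edge support is strictly greater than 50.
NJ with distance-based bootstrapping stands in for per-locus maximum
likelihood; it is consistent on additive and clean data (oracle-tested)
and fast enough to run thousands of loci on a laptop.

Trees are rooted on the edge separating the two clades when it exists
(midpoint rooting as fallback, flagged), with the root placed on that edge
so the two sides' maximum root-to-tip heights balance — this makes dating
exact on ultrametric input.  Node ages come from mean path lengths: for a
node v, MPL(v) is the mean path length from v to its descendant tips, and
age(v) = root_age · MPL(v)/MPL(root), with root_age = 9.5 Mya by default
(an intergeneric calibration).  MPL can invert parent/child ages on
non-clock trees; children are clipped to their parent's age and the tree
flagged.  Dating is scale-invariant in the branch lengths and reduces to
exact node heights on clock-like trees.

Divergence-time vectors per species pair (the MRCA age of the pair per
locus) are summarized as fixed-bin histograms (0.25 My default).  The
timing classifier takes the tallest bin as the main divergence mode and
calls "recent gene flow present" when more than 5% of loci are younger
than 0.2x the mode age; both thresholds are explicit configuration, since
the underlying expectation (a single peak under divergence-time gene flow
or ILS, an extra young peak under later introgression) is qualitative.
MRCA-age semantics are used even when a taxon is non-monophyletic in a
gene tree.

## Split networks

Genetic distances on the concatenated alignment (TN93 default, with
alignment-wide empirical base frequencies) feed a NeighborNet-style
construction: the standard agglomeration with net-divergence-adjusted
selection and 2/3–1/3 path reductions produces a circular taxon ordering,
and split weights are fitted by ordinary least squares constrained
non-negative (active-set NNLS) over all splits of that ordering; splits
with weight ≤ 1e-9 are dropped.  On additive (tree) distances this
recovers exactly the tree's splits and branch lengths.

The splits graph is realized as the planar dual of the chord arrangement
the splits induce on a disk: each split's chord crosses exactly the
chords of incompatible splits, cells of the arrangement are network
nodes, and each chord contributes one class of parallel edges whose
removal disconnects the graph into the split's two sides.  Deterministic
angular jitter keeps the arrangement generic (no concurrent chords).
Compatible systems reduce to trees; pairs of conflicting splits open
boxes.

Clade complexity is compared through node degrees.  Nodes are assigned to
a clade by their side of the inter-clade split (nearest-taxon graph
distance as fallback when no such split exists), degrees are taken on each
side's induced subgraph, and log E[degree] = β0 + β1·clade is fitted as a
Poisson GLM (statsmodels IRLS, deviance-converged; on this saturated
two-group design β1 is exactly the log ratio of mean degrees, which the
tests verify).  The node-to-clade assignment rule is a package decision —
published degree comparisons of joint networks rarely state one — so
absolute z-values depend on it.

## The simulator and its study conditions

`introphy.simulate` draws independent per-locus genealogies under a dated
species tree with per-branch diploid Ne (structured coalescent, pairwise
rate 1/(2Ne) per generation), one diploid individual per species by
default (two haploid lineages, matching the consensus input type).
Admixture is modelled as instantaneous pulses: backward in time, each
lineage in the destination branch at the pulse time moves to the source
branch with probability f — the discrete-hybridization picture rather
than continuous migration.  Sequences evolve site-independently (JC by
default, for its closed forms; GTR with discrete-gamma rates available),
haplotype pairs are collapsed to IUPAC consensus sequences, and loci are
concatenated on a single coordinate system so 50-kb jackknife blocks span
many exon-like loci.  There is no intra-locus recombination and no
selection.  Everything is deterministic given a seed; an f = 0 pulse is
dropped before simulation so it reproduces the no-pulse model exactly.

The default study conditions (in `introphy.calibration`) emulate a
two-clade radiation: ingroup ((P1,P2),P3) splitting at 1 and 2 Mya, a
two-taxon outgroup clade, root at 9.5 Mya, generation time 5 years,
mutation rate 1e-8 per site per generation (2e-9 per year, in the range
of avian estimates; no goose-specific rate is established, so these are
package defaults, not species facts), and diploid Ne = 1e5.  The ingroup
internal branch is then one coalescent unit, giving (2/3)e⁻¹ ≈ 24.5%
gene-tree discordance — substantial ILS for the D-statistic to absorb.
Datasets of 1000 x 1 kb loci give 1 Mb in 20 jackknife blocks.

The timing experiment uses its own scenario pair (shared demography, with
and without a pulse): Ne = 2e4, 300 x 5 kb loci, and a pulse of f = 0.3
from P3 into P2 at 0.05 Mya.  The choices follow from the diploid design
rather than convenience: a locus acquires a recent estimated P2–P3 age
only when *both* P2 haplotypes trace through the pulse (probability f²)
and all four P2/P3 haplotypes coalesce quickly (expectation ≈ 3·Ne
generations after the pulse), so at Ne = 1e5 a recent pulse produces no
young age peak at all, and an f large enough to dominate the histogram
would defeat the classifier's "smaller recent peak" assumption.  With
Ne = 2e4 and f = 0.3 the expected recent mass is ~0.1 — clearly present,
clearly secondary.

## What the synthetic data does and does not show

The simulator reproduces the features the statistics rely on: ILS
governed by branch lengths and Ne, directional pulse-induced ABBA/BABA
asymmetry, diploid heterozygosity as IUPAC codes, and finite loci on
block-compatible coordinates.  It omits recombination within loci,
mutation-rate variation across loci, selection, sequencing error,
alignment error and reference bias.  Passing tests therefore demonstrate
the correctness and calibration of the statistics under the stated model,
not robustness to those real-data complications.

## Numerical choices

- Consensus ties at floating-point resolution use a 1e-9 tolerance.
- Jackknife SE = 0 with D ≠ 0 yields Z = ±inf, p = 0, and is flagged via
  the degenerate-block count; fewer than two usable blocks is an error.
- NJ and NeighborNet break argmin ties by lowest index, making every tree
  and ordering deterministic.
- NNLS is scipy's active-set solver; the split-retention threshold is
  1e-9.
- GLM convergence: statsmodels' IRLS with tolerance 1e-10.
- MPL(root) = 0 (all-zero branch lengths) is an error; zero-length
  subtrees elsewhere date to their parent's age via clipping.
- Distance corrections reject p ≥ 0.75 (JC) or non-positive logarithm
  arguments (TN93) as saturated.

## Known limitations

- With the default 20 jackknife blocks the Z statistic has heavier tails
  than standard normal (roughly t with m−1 degrees of freedom, further
  widened when informative sites per block are few), so the realized
  |Z| > 3 false-positive rate on null data sits near 1–2% rather than the
  nominal 0.27%.  More blocks (longer genomes) tighten this; the p-values
  reported are the conventional normal-tail ones.

- Consensus-based gene-tree dating is nearly blind to recent gene flow
  between large populations (see the f²/Ne argument above); absence of a
  recent peak is weak evidence of absence.
- The D-statistic captures asymmetric gene flow only; symmetric exchange
  leaves D at zero and is not estimated.
- f (admixture fraction) estimation, five-taxon D extensions, and
  hybridization-network reconstruction are out of scope.
- The degree comparison depends on the node-to-clade assignment rule and
  on NNLS split filtering; compare like with like.
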