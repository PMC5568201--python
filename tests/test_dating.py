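"""Gene-tree pipeline: distances, NJ, bootstrap, MPL dating, timing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introphy.dating import (
    DatingConfig,
    DatingError,
    SaturationError,
    bootstrap_support,
    classify_timing,
    date_gene_trees,
    distance_matrix,
    filter_loci,
    mpl_date,
    nj_tree,
    pair_divergence_times,
    root_between_groups,
)
from introphy.trees import Tree

from conftest import make_alignment, tree_metric


class TestFilterLoci:
    def test_minimum_length_rule(self):
        loci = pd.DataFrame(
            {"locus_id": ["a", "b", "c"], "start": [0, 400, 900],
             "end": [400, 900, 1500]}
        )
        kept = filter_loci(loci, 500)
        assert list(kept["locus_id"]) == ["b", "c"]

    def test_zero_minimum_is_identity(self):
        loci = pd.DataFrame({"locus_id": ["a"], "start": [0], "end": [10]})
        assert len(filter_loci(loci, 0)) == 1


class TestDistanceMatrix:
    def test_identical_sequences_distance_zero(self):
        aln = make_alignment({"a": "ACGTACGT", "b": "ACGTACGT"})
        d = distance_matrix(aln)
        assert d.loc["a", "b"] == 0.0

    def test_jc_inverse_closed_form(self):
        # p = 0.0937 observed difference -> d = -(3/4) ln(1 - 4p/3) ~ 0.100
        n, k = 10_000, 937
        a = "A" * n
        b = "C" * k + "A" * (n - k)
        d = distance_matrix(make_alignment({"a": a, "b": b}))
        assert d.loc["a", "b"] == pytest.approx(
            -0.75 * np.log(1 - 4 * 0.0937 / 3), rel=1e-3
        )

    def test_saturated_pair_flagged(self):
        a = "ACGT" * 25
        b = "CATG" * 25  # 100% observed difference
        with pytest.raises(SaturationError):
            distance_matrix(make_alignment({"a": a, "b": b}))

    def test_heterozygote_half_mismatch(self):
        # R vs A: allele comparison mismatches with probability 0.5
        aln = make_alignment({"a": "R" * 100 + "A" * 900, "b": "A" * 1000})
        d_obs = distance_matrix(aln).loc["a", "b"]
        p = 0.5 * 0.1
        assert d_obs == pytest.approx(-0.75 * np.log(1 - 4 * p / 3), rel=1e-9)

    def test_pairwise_deletion_of_missing(self):
        aln = make_alignment({"a": "NNACGT", "b": "CCACGT"})
        assert distance_matrix(aln).loc["a", "b"] == 0.0

    def test_tn93_matches_r_ape_on_clean_alignment(self):
        # independent oracle: ape::dist.dna(model="TN93")
        import subprocess

        rows = {"a": "ACGTACGTAAGGCCTTACGATCGA" * 4,
                "b": "ACATACGTAGGGCCTCACGATCAA" * 4,
                "c": "GCGTACCTAAGGCTTTACGTTCGA" * 4}
        aln = make_alignment(rows)
        d = distance_matrix(aln, model="TN93")
        rscript = (
            'library(ape);'
            f's <- c(a="{rows["a"]}", b="{rows["b"]}", c="{rows["c"]}");'
            'x <- do.call(rbind, strsplit(tolower(s), ""));'
            'd <- dist.dna(as.DNAbin(x), model="TN93");'
            'cat(sprintf("%.10f", as.numeric(d)), sep="\\n")'
        )
        try:
            out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                                 text=True, timeout=120, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("Rscript/ape unavailable")
        ab, ac, bc = (float(v) for v in out.stdout.split())
        assert d.loc["a", "b"] == pytest.approx(ab, abs=1e-8)
        assert d.loc["a", "c"] == pytest.approx(ac, abs=1e-8)
        assert d.loc["b", "c"] == pytest.approx(bc, abs=1e-8)


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # distances from ((A:1,B:2):1,(C:3,D:4)): NJ must recover the
        # topology AB|CD with the generating branch lengths
        names = list("ABCD")
        m = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=names, columns=names, dtype=float,
        )
        tree = nj_tree(m)
        assert tree.bipartitions() == {frozenset("CD")}
        fitted = tree_metric(tree)
        assert np.allclose(fitted.loc[names, names].to_numpy(), m.to_numpy())
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxon_three_point_formulas(self):
        names = list("ABC")
        m = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=names, columns=names,
            dtype=float,
        )
        tree = nj_tree(m)
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_asymmetric_matrix_rejected(self):
        m = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(DatingError, match="symmetric"):
            nj_tree(m)

    def test_ultrametric_input_gives_clock_like_rooted_tree(self):
        names = list("ABCD")
        m = pd.DataFrame(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
            index=names, columns=names, dtype=float,
        )
        tree = nj_tree(m)
        rooted, on_edge = root_between_groups(
            tree, {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        )
        assert on_edge
        rooted.set_ages_from_lengths()
        depths = {l.name: rooted.root.age - 0.0 for l in rooted.leaves()}
        for leaf in rooted.leaves():
            # clock-like: all root-to-tip path lengths equal
            path = 0.0
            n = leaf
            while n.parent is not None:
                path += n.length
                n = n.parent
            assert path == pytest.approx(4.0)


class TestMplDating:
    def test_two_taxon_mrca_at_calibration(self):
        tree = Tree.from_newick("(A:3,B:7);")
        dated, _ = mpl_date(tree, root_age=9.5)
        assert dated.pair_mrca_ages()[frozenset("AB")] == pytest.approx(9.5)

    def test_hand_computed_three_taxon_age(self):
        # ((A:2,B:4):1,C:6): MPL(AB)=3, MPL(root)=14/3 -> age = 9.5*9/14
        tree = Tree.from_newick("((A:2,B:4):1,C:6);")
        dated, clipped = mpl_date(tree, root_age=9.5)
        assert not clipped
        ages = dated.pair_mrca_ages()
        assert ages[frozenset("AB")] == pytest.approx(9.5 * 9 / 14)
        assert ages[frozenset("AC")] == pytest.approx(9.5)

    def test_clock_like_tree_dated_exactly(self):
        tree = Tree.from_newick("((A:1,B:1):2,(C:2,D:2):1);")
        dated, clipped = mpl_date(tree, root_age=6.0)
        ages = dated.pair_mrca_ages()
        assert ages[frozenset("AB")] == pytest.approx(2.0, rel=1e-9)
        assert ages[frozenset("CD")] == pytest.approx(4.0, rel=1e-9)

    @given(c=st.floats(0.1, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        base = Tree.from_newick("((A:2,B:4):1,(C:3,D:1):2);")
        scaled = Tree.from_newick(
            f"((A:{2 * c},B:{4 * c}):{1 * c},(C:{3 * c},D:{1 * c}):{2 * c});"
        )
        a1 = mpl_date(base, 9.5)[0].pair_mrca_ages()
        a2 = mpl_date(scaled, 9.5)[0].pair_mrca_ages()
        for k in a1:
            assert a1[k] == pytest.approx(a2[k], rel=1e-9)

    def test_monotonicity_repair_flagged(self):
        # child MPL can exceed the parent's when subtree tips are distant
        tree = Tree.from_newick("((A:10,B:10):0.001,C:0.1);")
        dated, clipped = mpl_date(tree, 9.5)
        assert clipped
        for n in dated.preorder():
            if n.parent is not None:
                assert n.age <= n.parent.age + 1e-12

    def test_zero_length_tree_rejected(self):
        with pytest.raises(DatingError, match="zero-length"):
            mpl_date(Tree.from_newick("(A:0,B:0,C:0);"), 9.5)


class TestBootstrap:
    def test_clean_signal_full_support(self):
        rng = np.random.default_rng(0)
        backbone = "".join(rng.choice(list("ACGT"), 200))
        # 20 clade-diagnostic columns plus private autapomorphies per tip
        # (private columns carry no topological signal, so every replicate
        # containing any diagnostic column recovers ab|cd)
        clade = {"a": "C" * 20, "b": "C" * 20, "c": "A" * 20, "d": "A" * 20}
        private = {"a": "GAAA", "b": "AGAA", "c": "AAGA", "d": "AAAG"}
        rows = {t: backbone + clade[t] + private[t] for t in "abcd"}
        aln = make_alignment(rows)
        tree = nj_tree(distance_matrix(aln))
        mean = bootstrap_support(aln, tree, n_replicates=50, seed=0)
        assert mean == 100.0

    def test_same_seed_identical_supports(self):
        rng = np.random.default_rng(3)
        base = rng.choice(list("ACGT"), 120)
        rows = {}
        for t in "abcde":
            seq = base.copy()
            idx = rng.choice(120, 15, replace=False)
            seq[idx] = rng.choice(list("ACGT"), 15)
            rows[t] = "".join(seq)
        aln = make_alignment(rows)
        tree = nj_tree(distance_matrix(aln))
        s1 = bootstrap_support(aln, tree, 30, seed=7)
        s2 = bootstrap_support(aln, tree, 30, seed=7)
        assert s1 == s2

    def test_boundary_mean_support_excluded_by_filter(self):
        # mean of {60, 40} = 50 fails the strict > 50 rule
        cfg = DatingConfig()
        assert not (np.mean([60.0, 40.0]) > cfg.min_mean_support)


class TestTimingClassification:
    def test_concentrated_ages_labelled_during_divergence(self):
        rng = np.random.default_rng(0)
        ages = rng.normal(4.0, 0.3, size=500)
        tc = classify_timing(ages)
        assert tc.label == "gene flow during divergence"
        assert tc.recent_fraction == pytest.approx(0.0, abs=0.01)
        assert abs(tc.mode_age - 4.0) < 0.5

    def test_recent_mass_labelled_recent(self):
        rng = np.random.default_rng(1)
        ages = np.concatenate(
            [rng.normal(4.0, 0.3, 400), np.abs(rng.normal(0.2, 0.05, 100))]
        )
        tc = classify_timing(ages)
        assert tc.label == "recent gene flow present"
        assert tc.recent_fraction == pytest.approx(0.2, abs=0.03)

    def test_all_equal_ages(self):
        tc = classify_timing(np.full(30, 2.0))
        assert tc.recent_fraction == 0.0
        assert abs(tc.mode_age - 2.0) <= 0.25

    def test_underpowered_rejected(self):
        with pytest.raises(DatingError, match="20"):
            classify_timing(np.ones(10))


class TestLocusPipeline:
    def test_filter_report_matches_brute_force(self):
        from introphy.calibration import STUDY_GROUPS, study_model
        from introphy.simulate import LocusLayout, assemble_dataset

        ds = assemble_dataset(study_model(), LocusLayout(30, 600), seed=21)
        # make a third of the loci too short by editing the locus table
        loci = ds.alignment.loci.copy()
        loci.loc[::3, "end"] = loci.loc[::3, "start"] + 400
        ds.alignment.loci = loci
        cfg = DatingConfig(min_locus_length=500, n_bootstrap=20)
        dated, report = date_gene_trees(ds.alignment, STUDY_GROUPS, cfg, seed=1)
        short = set(report[report.status == "short"].locus_id)
        assert short == set(loci[(loci.end - loci.start) < 500].locus_id)
        dated_ids = {d.locus_id for d in dated}
        ok = report[report.status == "dated"]
        assert dated_ids == set(ok.locus_id)
        assert (ok.mean_support > 50).all()

    def test_age_error_decreases_with_locus_length(self):
        from introphy.calibration import STUDY_GROUPS, study_model
        from introphy.simulate import LocusLayout, assemble_dataset

        model = study_model()
        errors = {}
        for length in (500, 5000):
            ds = assemble_dataset(model, LocusLayout(40, length), seed=31)
            cfg = DatingConfig(min_mean_support=0, n_bootstrap=0)
            dated, _ = date_gene_trees(ds.alignment, STUDY_GROUPS, cfg, seed=1)
            est = pair_divergence_times(dated, ("P1", "P2"))
            true = []
            for t in ds.true_gene_trees:
                pm = t.pair_mrca_ages()
                cross = [v for k, v in pm.items()
                         if any(x.startswith("P1/") for x in k)
                         and any(x.startswith("P2/") for x in k)]
                true.append(np.mean(cross) * model.generation_time / 1e6)
            n = min(len(est), len(true))
            errors[length] = np.median(np.abs(np.asarray(est[:n]) - np.asarray(true[:n])))
        assert errors[5000] < errors[500]
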