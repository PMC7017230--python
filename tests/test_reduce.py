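import math
import subprocess

import numpy as np
import pytest

from consensify import (
    ScaffoldIndex,
    alignment_from_codes,
    build_alignment,
    jc69_distance,
    nj_tree,
    pcoa,
    variable_sites,
)
from consensify.reduce import DistanceMatrix, ReducedAlignment, read_distance_tsv, write_distance_tsv


def aln_from_strings(seqs: dict[str, str], scaffold_len: int | None = None) -> ReducedAlignment:
    length = scaffold_len or len(next(iter(seqs.values())))
    index = ScaffoldIndex((("scaf1", length),))
    return build_alignment({k: {"scaf1": v} for k, v in seqs.items()}, index)


def dm_from_array(mat, labels=None) -> DistanceMatrix:
    mat = np.asarray(mat, dtype=float)
    labels = tuple(labels or [f"t{i}" for i in range(len(mat))])
    return DistanceMatrix(
        labels, mat, np.zeros(mat.shape, dtype=np.int64), np.zeros(mat.shape, dtype=bool)
    )


class TestBuildAlignment:
    def test_columns_with_any_n_are_dropped(self):
        aln = aln_from_strings({"a": "ACNG", "b": "ACGG"})
        assert aln.n_sites == 3
        assert aln.positions.tolist() == [1, 2, 4]

    def test_n_free_inputs_fully_retained(self):
        aln = aln_from_strings({"a": "ACGT", "b": "ACGT"})
        assert aln.n_sites == 4
        assert aln.column(0) == "AA"

    def test_disjoint_missingness_intersects(self):
        aln = aln_from_strings({"a": "ANCGT", "b": "ACNGT"[:5], "c": "ACGNT"})
        # N at positions {2}, {3}, {4} respectively -> retain {1, 5}
        assert aln.positions.tolist() == [1, 5]

    def test_length_mismatch_names_culprit(self):
        index = ScaffoldIndex((("scaf1", 5),))
        with pytest.raises(ValueError, match="'b'.*'scaf1'"):
            build_alignment({"a": {"scaf1": "ACGTA"}, "b": {"scaf1": "ACG"}}, index)

    def test_removing_an_individual_never_loses_sites(self):
        rng = np.random.default_rng(5)
        seqs = {
            f"ind{i}": "".join(rng.choice(list("ACGTN"), p=[0.2] * 4 + [0.2], size=60))
            for i in range(4)
        }
        full = aln_from_strings(seqs, 60)
        for drop in seqs:
            subset = {k: v for k, v in seqs.items() if k != drop}
            sub = aln_from_strings(subset, 60)
            assert set(full.positions) <= set(sub.positions)

    def test_no_n_ever_in_output(self):
        aln = aln_from_strings({"a": "ANNNG", "b": "NCGTA"})
        assert (aln.matrix <= 3).all()


class TestVariableSites:
    def test_invariant_columns_dropped(self):
        aln = aln_from_strings({"a": "AAC", "b": "AAC", "c": "AAA"})
        out = variable_sites(aln)
        assert out.positions.tolist() == [3]

    def test_transition_columns_dropped_on_request(self):
        aln = aln_from_strings({"a": "AC", "b": "GC", "c": "GA"})
        # column 1: A/G transition; column 2: C/A transversion
        out = variable_sites(aln, remove_transitions=True)
        assert out.positions.tolist() == [2]

    def test_singleton_columns_dropped_on_request(self):
        aln = aln_from_strings({"a": "AA", "b": "CC", "c": "CA", "d": "CC"})
        # column 1 minor state A occurs once -> dropped; column 2 A twice -> kept
        out = variable_sites(aln, remove_singletons=True)
        assert out.positions.tolist() == [2]


class TestJC69:
    def test_identical_sequences_have_zero_distance(self):
        aln = aln_from_strings({"a": "ACGTACGT", "b": "ACGTACGT"})
        dm = jc69_distance(aln)
        assert dm.matrix[0, 1] == 0.0

    def test_ten_percent_p_distance(self):
        # 1 mismatch in 10 sites: d = -(3/4) ln(1 - 0.4/3)
        aln = aln_from_strings({"a": "ACGTACGTAC", "b": "ACGTACGTAG"})
        dm = jc69_distance(aln)
        assert dm.matrix[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert dm.matrix[0, 1] == pytest.approx(0.1073256, abs=1e-6)

    def test_jc_distance_dominates_p_distance(self):
        rng = np.random.default_rng(0)
        codes = {
            "a": rng.integers(0, 4, 500),
            "b": rng.integers(0, 4, 500),
            "c": rng.integers(0, 4, 500),
        }
        aln = alignment_from_codes(codes)
        from consensify.reduce import p_distance

        p = p_distance(aln)
        d = jc69_distance(aln).matrix
        off = ~np.eye(3, dtype=bool)
        assert (d[off] >= p[off]).all()

    def test_saturation_flagged_not_raised(self):
        # complementary sequences: p = 1 >= 3/4
        aln = aln_from_strings({"a": "AAAAAAAA", "b": "CCCCCCCC"})
        dm = jc69_distance(aln)
        assert dm.saturated[0, 1]
        assert np.isinf(dm.matrix[0, 1])


class TestNeighbourJoining:
    # additive distances from the tree ((a:2,b:3):3,(c:4,d:2):0); classic
    # four-taxon example with inter-tip path lengths entered directly
    ADDITIVE = np.array(
        [
            [0, 5, 9, 9],
            [5, 0, 10, 10],
            [9, 10, 0, 8],
            [9, 10, 8, 0],
        ],
        dtype=float,
    )

    def test_additive_matrix_recovered_exactly(self):
        dm = dm_from_array(self.ADDITIVE, "abcd")
        tree, newick = nj_tree(dm)
        # tip-to-tip path lengths on the NJ tree reproduce the input matrix
        for i, u in enumerate("abcd"):
            for j, v in enumerate("abcd"):
                if i < j:
                    dist = tree.find(u).distance(tree.find(v))
                    assert dist == pytest.approx(self.ADDITIVE[i, j], abs=1e-9)
        # and the split {a,b} | {c,d} is present
        names = {
            frozenset(t.name for t in clade.tips())
            for clade in tree.non_tips(include_self=False)
        }
        assert frozenset("ab") in names or frozenset("cd") in names

    def test_three_taxa_solve_three_point_equations(self):
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        dm = dm_from_array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]], "abc")
        tree, _ = nj_tree(dm)
        la = tree.find("a").length
        lb = tree.find("b").length
        lc = tree.find("c").length
        assert la == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lb == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lc == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_ultrametric_five_taxon_topology_recovered(self):
        # tree ((((a,b),c),d),e) with ultrametric depths 1, 2, 3, 4
        depth = {("a", "b"): 1, ("a", "c"): 2, ("b", "c"): 2}
        labels = "abcde"
        mat = np.zeros((5, 5))
        pair_depth = {
            ("a", "b"): 1, ("a", "c"): 2, ("b", "c"): 2,
            ("a", "d"): 3, ("b", "d"): 3, ("c", "d"): 3,
            ("a", "e"): 4, ("b", "e"): 4, ("c", "e"): 4, ("d", "e"): 4,
        }
        for (u, v), h in pair_depth.items():
            i, j = labels.index(u), labels.index(v)
            mat[i, j] = mat[j, i] = 2 * h
        tree, _ = nj_tree(dm_from_array(mat, labels), outgroup="e")
        clades = {
            frozenset(t.name for t in clade.tips())
            for clade in tree.non_tips(include_self=True)
        }
        assert frozenset("ab") in clades
        assert frozenset("abc") in clades
        assert frozenset("abcd") in clades

    def test_outgroup_rooting_splits_terminal_edge(self):
        dm = dm_from_array(self.ADDITIVE, "abcd")
        tree, newick = nj_tree(dm, outgroup="d")
        root_children = tree.children
        assert len(root_children) == 2
        sides = [
            {t.name for t in child.tips()} or {child.name} for child in root_children
        ]
        assert {"d"} in sides
        assert "d" in newick

    def test_fewer_than_three_taxa_rejected(self):
        dm = dm_from_array([[0, 1], [1, 0]], "ab")
        with pytest.raises(ValueError):
            nj_tree(dm)


class TestPCoA:
    def test_euclidean_distances_preserved(self):
        points = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0], [3.0, 4.0]])
        d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
        coords, eigvals = pcoa(dm_from_array(d))
        recon = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.allclose(recon, d, atol=1e-9)

    def test_two_taxa_at_distance_d(self):
        coords, eigvals = pcoa(dm_from_array([[0, 2.5], [2.5, 0]]))
        assert sorted(coords[:, 0]) == pytest.approx([-1.25, 1.25])

    def test_zero_matrix_gives_zero_coordinates(self):
        coords, eigvals = pcoa(dm_from_array(np.zeros((3, 3))))
        assert coords.shape[0] == 3
        assert np.allclose(coords, 0.0)

    def test_eigenvalue_sum_equals_centred_trace(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, eigvals = pcoa(dm_from_array(d))
        n = len(d)
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        assert eigvals.sum() == pytest.approx(np.trace(b), rel=1e-9)

    def test_eigenvalues_decreasing(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        _, eigvals = pcoa(dm_from_array(d))
        assert (np.diff(eigvals) <= 1e-12).all()


class TestDistanceTsvRoundTrip:
    def test_write_read_identity(self, tmp_path):
        dm = dm_from_array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]], "xyz")
        path = tmp_path / "d.tsv"
        write_distance_tsv(dm, str(path))
        back = read_distance_tsv(str(path))
        assert back.labels == dm.labels
        assert np.allclose(back.matrix, dm.matrix)


class TestAgainstApe:
    """Cross-check JC69 distances and NJ against the R package ape."""

    SEQS = {
        "t1": "ACGTACGTACGTACGTACGA",
        "t2": "ACGTACGTACGAACGTACGA",
        "t3": "ACGAACGTACGAACGTACGT",
        "t4": "TCGAACGAACGAACGTACGT",
    }

    def test_jc69_and_nj_match_ape(self, tmp_path):
        fasta = tmp_path / "aln.fa"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in self.SEQS.items()))
        out = tmp_path / "out"
        script = (
            f'a <- ape::read.dna("{fasta}", format="fasta");'
            f'd <- ape::dist.dna(a, model="JC69");'
            f'write.table(as.matrix(d), "{out}.dist.tsv", sep="\\t");'
            f'ape::write.tree(ape::nj(d), "{out}.nwk")'
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)

        aln = aln_from_strings(self.SEQS)
        dm = jc69_distance(aln)
        ape_rows = [
            line.split("\t")[1:]
            for line in (out.parent / "out.dist.tsv").read_text().strip().splitlines()[1:]
        ]
        ape_mat = np.array(ape_rows, dtype=float)
        assert np.allclose(dm.matrix, ape_mat, atol=1e-8)

        _, newick = nj_tree(dm)
        ape_newick = (out.parent / "out.nwk").read_text()
        # same unrooted topology: compare the non-trivial split
        import skbio

        ours = skbio.TreeNode.read([newick])
        theirs = skbio.TreeNode.read([ape_newick])
        assert ours.compare_rfd(theirs) == 0.0
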