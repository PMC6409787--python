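"""RT peptide extraction, protein distances, neighbor joining, assignment.

The NJ oracle is an exhaustive search over all unrooted topologies with
least-squares branch lengths, independent of the NJ implementation.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from retrodyn.lineage import (
    COPIA_LINEAGES,
    DistanceMatrix,
    RtPeptide,
    assign_lineage,
    cluster_lineages,
    extract_rt_peptide,
    mutate_peptide,
    nj_tree,
    protein_distance_matrix,
    reference_rt_peptides,
    to_newick,
)
from retrodyn.profiles import RT_COPIA, default_profiles
from retrodyn.simdata import encode_peptide
from retrodyn._seq import random_seq, revcomp


# ---------------------------------------------------------------------------
# exhaustive-topology oracle
# ---------------------------------------------------------------------------

def unrooted_topologies(labels):
    """All unrooted binary topologies as sets of nontrivial splits."""
    # recursive leaf insertion: every unrooted tree over n labels arises by
    # attaching the next leaf to every edge of every (n-1)-tree
    def trees(lbls):
        if len(lbls) == 3:
            return [(lbls[0], lbls[1], lbls[2])]
        out = []
        for sub in trees(lbls[:-1]):
            for i, edge in enumerate(_edges(sub)):
                out.append(_attach(sub, edge, lbls[-1]))
        return out

    def _edges(tree):
        # edges identified by path to subtree
        edges = []

        def walk(node, path):
            edges.append(path)
            if isinstance(node, tuple) and len(node) == 2:
                walk(node[0], path + (0,))
                walk(node[1], path + (1,))

        for i, child in enumerate(tree):
            walk(child, (i,))
        return edges

    def _attach(tree, path, leaf):
        def rebuild(node, p):
            if not p:
                return (node, leaf)
            node = list(node)
            node[p[0]] = rebuild(node[p[0]], p[1:])
            return tuple(node)

        return rebuild(tree, path)

    def splits(tree):
        out = set()

        def leafset(node):
            if isinstance(node, str):
                return frozenset([node])
            return frozenset().union(*(leafset(c) for c in node))

        def walk(node):
            ls = leafset(node)
            if 1 < len(ls) < len(labels) - 1:
                out.add(min(ls, key=sorted) and ls)
            if isinstance(node, tuple):
                for c in node:
                    walk(c)

        walk(tree)
        return frozenset(
            frozenset(s) for s in
            (min(ls, frozenset(labels) - ls, key=lambda x: sorted(x))
             for ls in out)
        )

    return [(t, splits(t)) for t in trees(list(labels))]


def tree_splits(tree, labels):
    """Nontrivial splits of a (rooted-representation) tree, canonicalised."""
    all_set = frozenset(labels)
    out = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        ls = frozenset(t.name for t in node.tips())
        if 1 < len(ls) < len(labels) - 1:
            out.add(min(ls, all_set - ls, key=lambda x: sorted(x)))
    return out


def ls_fit_error(splits, labels, dmat):
    """Least-squares branch-fit SSE for a topology given its split set."""
    # design matrix: columns = external edges + internal edges (splits)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    cols = [frozenset([lbl]) for lbl in labels] + list(splits)
    A = np.zeros((len(pairs), len(cols)))
    for pi, (i, j) in enumerate(pairs):
        for ci, part in enumerate(cols):
            # edge on path i-j iff the split separates i from j
            if (labels[i] in part) != (labels[j] in part):
                A[pi, ci] = 1.0
    y = np.array([dmat[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


class TestNeighborJoining:
    def test_four_taxa_additive_exact(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], float)
        tree = nj_tree(DistanceMatrix(labels, d))
        tips = {t.name: t for t in tree.tips()}
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            assert tips[a].distance(tips[b]) == pytest.approx(d[i, j])
        assert tree_splits(tree, labels) == {frozenset({"A", "B"})}

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj_tree(DistanceMatrix(["X", "Y", "Z"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"X": pytest.approx(0.5),
                           "Y": pytest.approx(1.5),
                           "Z": pytest.approx(2.5)}

    def test_five_taxa_vs_exhaustive_topology_oracle(self, rng):
        """NJ topology equals the least-squares-best topology over all 15
        unrooted 5-taxon trees, for additive distances from a random tree."""
        labels = list("ABCDE")
        # build a random additive matrix from the caterpillar
        # ((A,B),C),(D,E) with random positive branch lengths
        bl = dict(A=rng.uniform(0.5, 2), B=rng.uniform(0.5, 2),
                  C=rng.uniform(0.5, 2), D=rng.uniform(0.5, 2),
                  E=rng.uniform(0.5, 2), ab=rng.uniform(0.5, 2),
                  de=rng.uniform(0.5, 2))
        def dist(x, y):
            path = {
                frozenset("AB"): bl["A"] + bl["B"],
                frozenset("AC"): bl["A"] + bl["ab"] + bl["C"],
                frozenset("BC"): bl["B"] + bl["ab"] + bl["C"],
                frozenset("AD"): bl["A"] + bl["ab"] + bl["de"] + bl["D"],
                frozenset("AE"): bl["A"] + bl["ab"] + bl["de"] + bl["E"],
                frozenset("BD"): bl["B"] + bl["ab"] + bl["de"] + bl["D"],
                frozenset("BE"): bl["B"] + bl["ab"] + bl["de"] + bl["E"],
                frozenset("CD"): bl["C"] + bl["de"] + bl["D"],
                frozenset("CE"): bl["C"] + bl["de"] + bl["E"],
                frozenset("DE"): bl["D"] + bl["E"],
            }
            return path[frozenset(x + y)]
        d = np.zeros((5, 5))
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            d[i, j] = d[j, i] = dist(a, b)

        tree = nj_tree(DistanceMatrix(labels, d))
        nj_splits = tree_splits(tree, labels)
        topos = unrooted_topologies(labels)
        errors = [(ls_fit_error(sp, labels, d), sp) for _, sp in topos]
        best_err, best_splits = min(errors, key=lambda t: t[0])
        assert best_err == pytest.approx(0.0, abs=1e-18)
        assert nj_splits == best_splits
        # branch lengths exact on additive input
        tips = {t.name: t for t in tree.tips()}
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            assert tips[a].distance(tips[b]) == pytest.approx(d[i, j])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], float))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_newick_roundtrip(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        nwk = to_newick(nj_tree(DistanceMatrix(["X", "Y", "Z"], d)))
        assert nwk.endswith(";") and "X:" in nwk


class TestDistances:
    def test_identical_peptides_zero(self):
        p = RtPeptide("a", "copia", "MKLV" * 30, "query")
        q = RtPeptide("b", "copia", "MKLV" * 30, "query")
        r = RtPeptide("c", "copia", "MKLV" * 30, "query")
        m = protein_distance_matrix([p, q, r])
        assert np.allclose(m.values, 0.0)

    def test_five_of_hundred_substitutions(self):
        base = ("MKAQWERTYIPASDFGHKLCVNM" * 5)[:100]
        swapped = "".join("W" if c != "W" else "Y" for c in base[:5])
        mutated = swapped + base[5:]
        assert sum(a != b for a, b in zip(base, mutated)) == 5
        peps = [RtPeptide("a", "copia", base, "query"),
                RtPeptide("b", "copia", mutated, "query"),
                RtPeptide("c", "copia", base, "query")]
        m = protein_distance_matrix(peps)
        assert m.values[0, 1] == pytest.approx(0.05)

    def test_symmetry_and_zero_diagonal(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        peps = [
            RtPeptide(f"p{i}", "gypsy",
                      "".join(aas[j] for j in rng.integers(0, 20, 80)),
                      "query")
            for i in range(4)
        ]
        m = protein_distance_matrix(peps)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)


class TestRtExtraction:
    @staticmethod
    def element_with_rt(offset: int, reverse: bool = False):
        from retrodyn.discover import LTRElement
        rng = np.random.default_rng(41)
        prof = default_profiles()[RT_COPIA]
        cds = encode_peptide(prof.consensus)
        internal = (random_seq(rng, 1000 + offset) + cds
                    + random_seq(rng, 800))
        seq = random_seq(rng, 300) + internal + random_seq(rng, 300)
        if reverse:
            seq = revcomp(seq)
        return LTRElement(
            id="el", contig="c", start=0, end=len(seq),
            ltr5_start=0, ltr5_end=300, ltr3_start=len(seq) - 300,
            ltr3_end=len(seq), ltr_similarity=100.0,
            domains_found=frozenset({RT_COPIA}), superfamily="copia",
            sequence=seq,
        ), prof.consensus

    @pytest.mark.parametrize("offset", [0, 1, 2])
    def test_recovered_from_any_frame(self, offset):
        el, consensus = self.element_with_rt(offset)
        assert extract_rt_peptide(el).sequence == consensus

    def test_recovered_from_reverse_strand(self):
        el, consensus = self.element_with_rt(0, reverse=True)
        assert extract_rt_peptide(el).sequence == consensus

    def test_missing_rt_domain_is_an_error(self):
        el, _ = self.element_with_rt(0)
        el.domains_found = frozenset({"GAG"})
        with pytest.raises(ValueError, match="filter"):
            extract_rt_peptide(el)


class TestAssignment:
    def test_mutated_exemplar_assigned_to_its_lineage(self):
        refs = reference_rt_peptides("copia")
        for lineage in ("Ale", "TAR", "Bianca"):
            src = next(r for r in refs if r.lineage == lineage)
            q = RtPeptide("q", "copia", mutate_peptide(src.sequence, 0.08, 5),
                          "query")
            calls = cluster_lineages([q], refs)
            assert calls["q"] == (lineage, False)

    def test_superfamilies_clustered_separately(self):
        copia_refs = reference_rt_peptides("copia")
        gypsy_refs = reference_rt_peptides("gypsy")
        src = next(r for r in copia_refs if r.lineage == "Ale")
        q = RtPeptide("q", "copia", mutate_peptide(src.sequence, 0.1, 2),
                      "query")
        calls = cluster_lineages([q], copia_refs + gypsy_refs)
        gypsy_lineages = {r.lineage for r in gypsy_refs}
        assert calls["q"][0] not in gypsy_lineages
        assert calls["q"][0] in set(COPIA_LINEAGES)

    def test_equidistant_query_flagged_ambiguous(self):
        # symmetric hand-built matrix: q exactly between two references
        labels = ["q", "L1_ref", "L2_ref"]
        d = np.array([[0, 1.0, 1.0],
                      [1.0, 0, 1.6],
                      [1.6, 1.0, 0]], float)
        d = (d + d.T) / 2
        tree = nj_tree(DistanceMatrix(labels, d))
        calls = assign_lineage(tree, ["q"],
                               {"L1_ref": "L1", "L2_ref": "L2"})
        lineage, ambiguous = calls["q"]
        assert ambiguous
        assert lineage in {"L1", "L2"}

    def test_no_references_is_an_error(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        with pytest.raises(ValueError):
            assign_lineage(tree, ["a"], {})
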