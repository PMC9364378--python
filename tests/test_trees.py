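"""Newick reformatting, support collapsing, RF distances, NJ fallback."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from corephylo.errors import ConfigError, ParseError
from corephylo.trees import (
    collapse_low_support,
    nj_tree,
    random_nni,
    read_tree,
    reformat_support_newick,
    rf_distance,
    rf_null_test,
    write_tree,
)


class TestReformat:
    def test_bracketed_support_moved_to_label(self):
        out = reformat_support_newick("((A:1,B:1):0.5[87],C:1);")
        assert out == "((A:1,B:1)87:0.5,C:1);"
        t = read_tree(out)
        labels = [nd.label for nd in t.preorder_internal_node_iter() if nd.label]
        assert labels == ["87"]

    def test_no_brackets_unchanged(self):
        s = "((A:1,B:1)95:0.5,C:1);"
        assert reformat_support_newick(s) == s

    def test_round_trip_topology_and_supports(self):
        raw = "(((A:1,B:1):0.5[87],C:1):0.2[55],(D:1,E:1):0.9[100]);"
        t = read_tree(reformat_support_newick(raw))
        again = read_tree(write_tree(t))
        assert rf_distance(t, again).raw == 0
        sups = sorted(nd.label for nd in again.preorder_internal_node_iter() if nd.label)
        assert sups == ["100", "55", "87"]

    def test_unbalanced_parens_rejected(self):
        with pytest.raises(ParseError, match="offset"):
            reformat_support_newick("((A,B):1[5],C));")
        with pytest.raises(ParseError):
            reformat_support_newick("((A,B):1[5,C);")


class TestCollapse:
    def _tree(self, s1, s2):
        return read_tree(f"(((A:1,B:1){s1}:1,C:1){s2}:1,(D:1,E:1)100:1,F:1);")

    def test_below_ten_collapsed_at_ten_kept(self):
        t = collapse_low_support(self._tree(9, 10))
        labels = [nd.label for nd in t.preorder_internal_node_iter() if nd.label]
        assert "9" not in labels and "10" in labels

    def test_full_support_unchanged(self):
        t = self._tree(100, 100)
        out = collapse_low_support(t)
        assert rf_distance(t, out).raw == 0

    def test_collapse_all_gives_star(self):
        t = read_tree("(((A:1,B:1)5:1,C:1)3:1,(D:1,E:1)2:1,F:1);")
        out = collapse_low_support(t)
        assert len(rf_nontrivial(out)) == 0

    def test_unlabeled_nodes_never_collapsed(self):
        t = read_tree("(((A:1,B:1):1,C:1):1,D:1,E:1);")
        out = collapse_low_support(t)
        assert rf_distance(t, out).raw == 0

    def test_proportion_scale_autodetected(self):
        t = read_tree("(((A:1,B:1)0.05:1,C:1)0.9:1,D:1,E:1);")
        out = collapse_low_support(t)
        labels = [nd.label for nd in out.preorder_internal_node_iter() if nd.label]
        assert labels == ["0.9"]

    def test_idempotent(self):
        t = self._tree(5, 50)
        once = collapse_low_support(t)
        twice = collapse_low_support(once)
        assert rf_distance(once, twice).raw == 0

    def test_collapsing_reduces_bipartitions(self):
        t = self._tree(5, 50)
        assert len(rf_nontrivial(collapse_low_support(t))) < len(rf_nontrivial(t))


def rf_nontrivial(tree):
    from corephylo.trees import _nontrivial_bipartitions

    return _nontrivial_bipartitions(tree)


class TestRF:
    def test_identical_zero(self):
        t1 = read_tree("((A,B),(C,D),E);")
        t2 = read_tree("((A,B),(C,D),E);")
        r = rf_distance(t1, t2)
        assert r.raw == 0 and r.normalized == 0.0

    def test_five_leaf_hand_example(self):
        t1 = read_tree("((A,B),C,(D,E));")
        t2 = read_tree("((A,C),B,(D,E));")
        r = rf_distance(t1, t2)
        assert r.raw == 2
        assert r.normalized == pytest.approx(0.5)
        assert r.shared == 1

    def test_leafset_mismatch_lists_difference(self):
        with pytest.raises(ConfigError, match="F"):
            rf_distance(read_tree("((A,B),C);"), read_tree("((A,B),F);"))

    def test_random_binary_pairs_against_dendropy(self):
        """Cross-check raw RF against dendropy's bipartition machinery."""
        rng = np.random.default_rng(0)
        taxa = [f"T{i}" for i in range(8)]
        for trial in range(10):
            tns = dendropy.TaxonNamespace(taxa)
            t1 = dendropy.simulate.treesim.uniform_pure_birth_tree(
                birth_rate=1.0, taxon_namespace=tns, rng=_PyRng(rng)
            )
            t2 = dendropy.simulate.treesim.uniform_pure_birth_tree(
                birth_rate=1.0, taxon_namespace=tns, rng=_PyRng(rng)
            )
            t1.is_rooted = t2.is_rooted = False
            t1.update_bipartitions()
            t2.update_bipartitions()
            mine = rf_distance(read_tree(_nwk(t1)), read_tree(_nwk(t2))).raw
            theirs = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
            assert mine == theirs

    def test_permutation_of_leaf_order_invariant(self):
        t1 = read_tree("((A,B),(C,D),E);")
        t2 = read_tree("(E,(D,C),(B,A));")
        assert rf_distance(t1, t2).raw == 0


def _nwk(t):
    return t.as_string(schema="newick", suppress_rooting=True)


class _PyRng:
    """Adapter: numpy Generator -> the random.Random subset dendropy uses."""

    def __init__(self, rng):
        self._rng = rng

    def sample(self, population, k):
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def expovariate(self, lam):
        return float(self._rng.exponential(1.0 / lam))

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def random(self):
        return float(self._rng.random())

    def choice(self, seq):
        return seq[int(self._rng.integers(0, len(seq)))]

    def shuffle(self, seq):
        self._rng.shuffle(seq)


class TestNullTest:
    def _base(self, n=12):
        taxa = [f"T{i}" for i in range(n)]
        rng = np.random.default_rng(1)
        order = list(rng.permutation(taxa))
        nwk = "(" + ",".join(order[:2]) + ""
        t = "(" + order[0] + "," + order[1] + ")"
        for x in order[2:]:
            t = f"({t},{x})"
        return read_tree(t + ";")

    def test_nni_outlier_flagged(self):
        best = self._base()
        replicates = [random_nni(best, n_moves=1, seed=s) for s in range(12)]
        far = random_nni(best, n_moves=10, seed=99)
        report = rf_null_test(best, replicates, {"far": far})
        assert report.exceeds["far"]
        assert report.percentile["far"] == 1.0

    def test_observed_within_null_not_exceeding(self):
        best = self._base()
        replicates = [random_nni(best, n_moves=1, seed=s) for s in range(12)]
        report = rf_null_test(best, replicates, {"probe": 0.0})
        report2 = rf_null_test(best, replicates, {"m": report.null_max})
        assert not report2.exceeds["m"]
        assert report2.percentile["m"] < 1.0

    def test_identical_tree_not_exceeding(self):
        best = self._base()
        replicates = [random_nni(best, n_moves=1, seed=s) for s in range(5)]
        report = rf_null_test(best, replicates, {"same": best})
        assert report.observed["same"] == 0.0
        assert not report.exceeds["same"]
        assert report.percentile["same"] == 0.0

    def test_requires_two_replicates(self):
        best = self._base()
        with pytest.raises(ConfigError):
            rf_null_test(best, [best], {})


class TestNJ:
    def test_additive_four_taxon_recovery(self):
        # tree ((A,B),(C,D)) with internal branch 2 and tip branches 1
        ids = ["A", "B", "C", "D"]
        d = pd.DataFrame(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            index=ids,
            columns=ids,
            dtype=float,
        )
        t = nj_tree(d)
        expected = read_tree("((A,B),(C,D));")
        assert rf_distance(t, expected).raw == 0

    def test_three_taxa_trivial(self):
        ids = ["A", "B", "C"]
        d = pd.DataFrame([[0, 1, 2], [1, 0, 2], [2, 2, 0]], index=ids, columns=ids, dtype=float)
        t = nj_tree(d)
        assert {l.taxon.label for l in t.leaf_node_iter()} == set(ids)

    def test_asymmetric_rejected(self):
        ids = ["A", "B"]
        d = pd.DataFrame([[0, 1], [2, 0]], index=ids, columns=ids, dtype=float)
        with pytest.raises(ConfigError):
            nj_tree(d)

    def test_pns_distance_tree_separates_groups(self, small_dataset):
        """Zero-noise shortcut: NJ on true core sequence distances keeps the
        two simulated groups on disjoint sides."""
        genomes, calls, truth = small_dataset
        ids = list(genomes)
        seqs = {
            g: "".join(truth.core_sequences[gene][g] for gene in truth.core_gene_functions[:20])
            for g in ids
        }
        n = len(ids)
        d = pd.DataFrame(0.0, index=ids, columns=ids)
        for a, b in itertools.combinations(ids, 2):
            mism = sum(1 for x, y in zip(seqs[a], seqs[b]) if x != y) / len(seqs[a])
            d.loc[a, b] = d.loc[b, a] = mism
        t = nj_tree(d)
        group_of = {g: truth.group_assignment[truth.species_assignment[g]] for g in ids}
        a_leaves = frozenset(g for g in ids if group_of[g] == "A")
        assert a_leaves in rf_nontrivial(t) or frozenset(set(ids) - a_leaves) in rf_nontrivial(t)


class TestExports:
    def test_multiphylo_one_newick_per_line(self, tmp_path):
        from corephylo.trees import write_multiphylo

        trees = [read_tree("((A,B),C);"), read_tree("((A,C),B);")]
        p = tmp_path / "genes.trees"
        write_multiphylo(trees, p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 2 and all(l.endswith(";") for l in lines)

    def test_nexus_taxpartition_block(self, tmp_path):
        from corephylo.alignment import GeneAlignment, concatenate
        from corephylo.trees import export_nexus_with_taxa_blocks

        sm = concatenate(
            [GeneAlignment(gene_id="g", sequences={"G1": "ATGAAA", "G2": "ATGAAA"})], ["G1", "G2"]
        )
        p = tmp_path / "sm.nex"
        export_nexus_with_taxa_blocks(sm, {"G1": "sp1", "G2": "sp1"}, p)
        text = p.read_text()
        assert text.startswith("#NEXUS")
        assert "NTAX=2 NCHAR=6" in text
        assert "TAXPARTITION SPECIES" in text
        assert "sp1 : G1 G2" in text
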