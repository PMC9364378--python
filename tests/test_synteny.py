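"""Links, synteny index, and reference-guided scaffold reordering."""

import numpy as np
import pandas as pd
import pytest

from corephylo.errors import ConfigError
from corephylo.simulate import SimConfig, fragment_assembly, simulate_dataset
from corephylo.synteny import (
    LinkSet,
    choose_reference_genome,
    consensus_network,
    conserved_link_profile,
    extract_links,
    link_occurrence_matrix,
    order_links,
    orient_scaffolds,
    reorder_all,
    reorder_draft,
    score_scaffolds,
    si_matrix,
    species_link_presence,
    synteny_index,
)


class TestExtractLinks:
    def test_circular_order(self):
        ls = extract_links([list("ABCDE")], circular=True)
        assert ls.links == {frozenset(p) for p in ["AB", "BC", "CD", "DE", "EA"]}
        assert ls.n_links == 5

    def test_two_scaffolds_linear(self):
        ls = extract_links([["A", "B"], ["C", "D"]], circular=False)
        assert ls.links == {frozenset("AB"), frozenset("CD")}

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ConfigError):
            extract_links([["A", "B", "A"]], circular=True)

    def test_single_gene_rejected(self):
        with pytest.raises(ConfigError):
            extract_links([["A"]], circular=True)

    def test_full_panel_n_links_equals_panel_size(self):
        genes = [f"g{i}" for i in range(384)]
        ls = extract_links([genes], circular=True)
        assert ls.n_links == 384


class TestSyntenyIndex:
    def test_identical_orders_one(self):
        a = extract_links([list("ABCDEFGH")], circular=True)
        assert synteny_index(a, a) == 1.0

    def test_hand_example_point_six(self):
        a = extract_links([list("ABCDE")], circular=True)
        b = extract_links([list("ABDCE")], circular=True)
        # shared links: AB, CD, EA
        assert synteny_index(a, b) == pytest.approx(0.6)

    def test_disjoint_orders_zero(self):
        genes = [f"g{i}" for i in range(50)]
        base = order_links(genes, circular=True)
        rng = np.random.default_rng(0)
        for _ in range(500):
            perm = list(rng.permutation(genes))
            if not (order_links(perm, circular=True) & base):
                assert synteny_index(base, order_links(perm, circular=True)) == 0.0
                return
        pytest.fail("no disjoint permutation found")

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        a = order_links(list(rng.permutation(genes)), circular=True)
        b = order_links(list(rng.permutation(genes)), circular=True)
        assert synteny_index(a, b) == synteny_index(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            synteny_index(set(), {frozenset("AB")})


class TestScoreScaffolds:
    def test_hand_example(self):
        ref = [f"g{i}" for i in range(1, 7)]
        ordered, dropped = score_scaffolds({"S1": ["g4", "g5"], "S2": ["g1", "g2", "g3"]}, ref)
        assert ordered == ["S2", "S1"]
        assert dropped == []

    def test_single_scaffold(self):
        ordered, _ = score_scaffolds({"S1": ["g1", "g2"]}, ["g1", "g2", "g3"])
        assert ordered == ["S1"]

    def test_tie_broken_by_id(self):
        ref = ["g1", "g2", "g3", "g4"]
        ordered, _ = score_scaffolds({"SB": ["g2", "g3"], "SA": ["g3", "g2"]}, ref)
        assert ordered == ["SA", "SB"]

    def test_scaffold_without_reference_genes_dropped(self):
        ordered, dropped = score_scaffolds({"S1": ["g1"], "S2": ["x1"]}, ["g1", "g2"])
        assert ordered == ["S1"] and dropped == ["S2"]

    def test_wraparound_arc_ordering(self):
        # arc spanning the linearization origin must slot between its
        # neighbours, not in the middle of the order
        ref = [f"g{i}" for i in range(10)]
        scaffolds = {"S1": ["g9", "g0", "g1"], "S2": ["g2", "g3", "g4"], "S3": ["g5", "g6", "g7"]}
        ordered, _ = score_scaffolds(scaffolds, ref)
        # as a circle: S1 then S2 then S3 (any rotation of it)
        idx = {s: i for i, s in enumerate(ordered)}
        assert (idx["S2"] - idx["S1"]) % 3 == 1
        assert (idx["S3"] - idx["S2"]) % 3 == 1


class TestOrientAndReorder:
    def test_fragmentation_recovery_si_one(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        ref_links = order_links(genes, circular=True)
        for trial in range(10):
            # random arcs of the circle, random flips, shuffled order
            cuts = sorted(rng.choice(40, size=5, replace=False))
            arcs = []
            for a, b in zip(cuts, list(cuts[1:]) + [cuts[0] + 40]):
                arc = [genes[k % 40] for k in range(a, b)]
                if rng.random() < 0.5:
                    arc = arc[::-1]
                arcs.append(arc)
            rng.shuffle(arcs)
            scaffolds = {f"S{i}": arc for i, arc in enumerate(arcs)}
            cfg = reorder_draft("draft", scaffolds, {"REF": genes})
            assert cfg.si == 1.0
            assert cfg.best_reference == "REF"
            assert order_links(cfg.gene_order, circular=True) == ref_links

    def test_pool_of_one_reference(self):
        cfg = reorder_draft("d", {"S1": ["g1", "g2"], "S2": ["g3", "g4"]}, {"R": ["g1", "g2", "g3", "g4"]})
        assert cfg.best_reference == "R"
        assert cfg.si == 1.0

    def test_matching_reference_selected(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(30)]
        other = list(rng.permutation(genes))
        scaffolds = {"S1": genes[:10], "S2": genes[10:20], "S3": genes[20:]}
        cfg = reorder_draft("d", scaffolds, {"RA": other, "RB": genes})
        assert cfg.best_reference == "RB"
        assert cfg.si == 1.0

    def test_single_gene_scaffold_kept_forward(self):
        cfg = orient_scaffolds(["S1"], {"S1": ["g1", "g2"]}, set(), genome_id="d")
        assert cfg.scaffold_order == [("S1", "forward")]

    def test_reorder_all_grows_pool_and_is_deterministic(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        drafts = []
        for i, n_sc in [(1, 3), (2, 5)]:
            cuts = sorted(rng.choice(30, size=n_sc, replace=False))
            arcs = [[genes[k % 30] for k in range(a, b)] for a, b in zip(cuts, list(cuts[1:]) + [cuts[0] + 30])]
            drafts.append((f"D{i}", {f"S{j}": arc for j, arc in enumerate(arcs)}, 1000 - i, n_sc))
        out1 = reorder_all(drafts, {"REF": genes})
        out2 = reorder_all(drafts, {"REF": genes})
        assert all(out1[k].gene_order == out2[k].gene_order for k in out1)
        assert all(out1[k].si == 1.0 for k in out1)

    def test_reorder_all_requires_reference(self):
        with pytest.raises(ConfigError):
            reorder_all([], {})

    def test_draft_without_core_genes_rejected(self):
        with pytest.raises(ConfigError):
            reorder_draft("d", {"S1": []}, {"R": ["g1", "g2"]})


class TestConsensus:
    def _presence(self, freq_a, freq_b, n=100):
        rows = {}
        for i in range(n):
            rows[f"spA{i}"] = [int(i < freq_a)]
            rows[f"spB{i}"] = [int(i < freq_b)]
        df = pd.DataFrame.from_dict(rows, orient="index", columns=["x|y"])
        groups = {f"spA{i}": "A" for i in range(n)}
        groups.update({f"spB{i}": "B" for i in range(n)})
        return df, groups

    def test_majority_in_one_group_kept(self):
        df, groups = self._presence(60, 40)
        c = consensus_network(df, groups)
        row = c.iloc[0]
        assert row["kept"] and row["dominant_group"] == "A"
        assert row["freq_A"] == pytest.approx(0.6)

    def test_exactly_half_everywhere_discarded(self):
        df, groups = self._presence(50, 50)
        c = consensus_network(df, groups)
        assert not c.iloc[0]["kept"]

    def test_everywhere_kept(self):
        df, groups = self._presence(100, 100)
        c = consensus_network(df, groups)
        assert c.iloc[0]["kept"]


class TestProfiles:
    def test_single_species_all_links_present(self):
        genes = ["g1", "g2", "g3", "g4"]
        ls = extract_links([genes], circular=True, genome_id="G1")
        occ = link_occurrence_matrix([ls])
        pres = species_link_presence(occ, {"G1": "S1"})
        prof = conserved_link_profile("G1", genes, pres, {"S1": "A"})
        assert (prof["freq_A"] == 1.0).all()
        assert len(prof) == 4

    def test_reference_choice_max_mean_si_ties_lexicographic(self):
        si = pd.DataFrame(
            [[1.0, 0.5, 0.8], [0.5, 1.0, 0.8], [0.8, 0.8, 1.0]],
            index=["G2", "G1", "G3"],
            columns=["G2", "G1", "G3"],
        )
        assert choose_reference_genome(si) == "G3"
        tie = pd.DataFrame(1.0, index=["GB", "GA"], columns=["GB", "GA"])
        assert choose_reference_genome(tie) == "GA"

    def test_group_specific_inversion_breakpoint_links(self):
        genes = [f"g{i}" for i in range(12)]
        inverted = genes[:3] + genes[3:8][::-1] + genes[8:]
        ls1 = extract_links([genes], circular=True, genome_id="G1")
        ls2 = extract_links([inverted], circular=True, genome_id="G2")
        occ = link_occurrence_matrix([ls1, ls2])
        pres = species_link_presence(occ, {"G1": "S1", "G2": "S2"})
        prof = conserved_link_profile("G1", genes, pres, {"S1": "A", "S2": "B"})
        differs = prof[prof["freq_A"] != prof["freq_B"]]["link"].tolist()
        # exactly the two links spanning the inversion breakpoints
        assert sorted(differs) == sorted(["g2|g3", "g7|g8"])


def test_si_matrix_properties(small_dataset):
    genomes, calls, truth = small_dataset
    linksets = [
        extract_links([truth.true_gene_orders[g]], circular=True, genome_id=g) for g in list(genomes)[:6]
    ]
    si = si_matrix(linksets)
    assert np.allclose(np.diag(si.values), 1.0)
    assert np.allclose(si.values, si.values.T)
    assert ((si.values >= 0) & (si.values <= 1)).all()


def test_simulated_draft_reordering_recovers_truth():
    """Drafts fragmented from unrearranged genomes recover SI=1 and the true
    circular link set via the full reorder_all sweep."""
    cfg = SimConfig(
        n_groups=1,
        species_per_group=3,
        genomes_per_species=2,
        core_panel_size=50,
        accessory_pool_size=40,
        rearrangement_rate=0.0,
        draft_fraction=0.0,
        gene_split_probability=0.0,
        noise_annotation_rates={},
        mean_gene_length_codons=60,
        seed=41,
    )
    genomes, calls, truth = simulate_dataset(cfg)
    ids = list(genomes)
    refs = {gid: truth.true_gene_orders[gid] for gid in ids[:2]}
    drafts = []
    rng = np.random.default_rng(0)
    for gid in ids[2:]:
        rec, gcalls = genomes[gid], [c for c in calls if c.genome_id == gid]
        frag, fcalls = fragment_assembly(rec, gcalls, n_scaffolds=6, rng=rng)
        core = set(truth.core_gene_functions)
        scaffolds = {}
        for c in sorted(fcalls, key=lambda c: (c.scaffold_id, c.start)):
            if c.function in core:
                scaffolds.setdefault(c.scaffold_id, []).append(c.function)
        drafts.append((gid, scaffolds, frag.n50, len(frag.scaffolds)))
    out = reorder_all(drafts, refs)
    for gid, cfg_out in out.items():
        assert cfg_out.si == 1.0
        assert order_links(cfg_out.gene_order, circular=True) == order_links(
            truth.true_gene_orders[gid], circular=True
        )


class TestExports:
    def _consensus(self):
        df = pd.DataFrame.from_dict(
            {"sp1": [1, 1], "sp2": [1, 0]}, orient="index", columns=["gA|gB", "gB|gC"]
        )
        return consensus_network(df, {"sp1": "A", "sp2": "A"})

    def test_sif_lists_kept_links(self, tmp_path):
        from corephylo.synteny import write_sif

        p = tmp_path / "net.sif"
        write_sif(self._consensus(), p)
        lines = p.read_text().strip().splitlines()
        assert "gA\tlink\tgB" in lines

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        from corephylo.synteny import write_graphml

        p = tmp_path / "net.graphml"
        write_graphml(self._consensus(), p)
        g = nx.read_graphml(p)
        assert set(map(frozenset, g.edges())) == {frozenset(("gA", "gB"))}

    def test_dotplot_identity_diagonal(self):
        from corephylo.synteny import dotplot_coordinates

        genes = [f"g{i}" for i in range(10)]
        df = dotplot_coordinates(genes, genes)
        assert (df["relative_position_a"] == df["relative_position_b"]).all()
        assert len(df) == 10
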