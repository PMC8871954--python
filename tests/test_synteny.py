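"""dcw karyotype encoding, paralog selection, status calls, adjacency parsimony."""

import numpy as np
import pandas as pd
import pytest

from conftest import exhaustive_mpr_sets
from traitlab import simulate
from traitlab.synteny import (DCW_FAMILIES, EncodedKaryotype, classify_status,
                              encode_karyotype, fitch_state_sets,
                              karyotype_adjacencies,
                              reconstruct_ancestral_adjacencies,
                              select_paralog, write_procars_input)
from traitlab.tree import read_newick


def order_rows(genome, entries, molecule="chr", start_index=1):
    """entries: list of (family, strand) laid out contiguously."""
    return [{"genome": genome, "molecule": molecule, "index": start_index + i,
             "strand": s, "family": f} for i, (f, s) in enumerate(entries)]


FULL = [(f, "+") for f in DCW_FAMILIES]


class TestEncodeKaryotype:
    def test_contiguous_cluster_single_chromosome(self):
        kar = encode_karyotype(pd.DataFrame(order_rows("g", FULL)))
        assert [len(c) for c in kar.chromosomes] == [17]
        assert kar.telomere_log == []

    def test_distant_gene_split_off(self):
        rows = order_rows("g", [(f, "+") for f in DCW_FAMILIES if f != "murA"])
        rows.append({"genome": "g", "molecule": "chr", "index": 316,
                     "strand": "+", "family": "murA"})
        kar = encode_karyotype(pd.DataFrame(rows), gap_threshold=5)
        assert sorted(len(c) for c in kar.chromosomes) == [1, 16]
        assert len(kar.telomere_log) == 1

    def test_infinite_threshold_never_splits(self):
        rows = order_rows("g", [(f, "+") for f in DCW_FAMILIES if f != "murA"])
        rows.append({"genome": "g", "molecule": "chr", "index": 316,
                     "strand": "+", "family": "murA"})
        kar = encode_karyotype(pd.DataFrame(rows), gap_threshold=np.inf)
        assert [len(c) for c in kar.chromosomes] == [17]

    def test_kb_mode_uses_start_coordinates(self):
        rows = [{"genome": "g", "molecule": "chr", "index": i + 1, "strand": "+",
                 "family": f, "start": 1000 * (i + 1)}
                for i, f in enumerate(DCW_FAMILIES[:3])]
        rows.append({"genome": "g", "molecule": "chr", "index": 5, "strand": "+",
                     "family": "murB", "start": 60_000})
        kar = encode_karyotype(pd.DataFrame(rows), gap_threshold=10_000, mode="kb")
        assert sorted(len(c) for c in kar.chromosomes) == [1, 3]

    def test_tandem_copies_collapse(self):
        rows = order_rows("g", [("murC", "+"), ("murC", "+"), ("murB", "+")])
        kar = encode_karyotype(pd.DataFrame(rows))
        assert kar.chromosomes == [[("murC", 1), ("murB", 1)]]
        assert kar.paralog_log == []  # tandem needs no selection


class TestSelectParalog:
    def test_rule1_cluster_context(self):
        rows = order_rows("g", [(f, "+") for f in DCW_FAMILIES[:11]])
        rows.append({"genome": "g", "molecule": "plasmid", "index": 1,
                     "strand": "+", "family": "mraZ"})
        kar = encode_karyotype(pd.DataFrame(rows))
        assert kar.paralog_log == [("g", "mraZ", "cluster-context")]
        assert sorted(len(c) for c in kar.chromosomes) == [11]

    def test_rule2_main_molecule(self):
        # two singleton copies, zero cluster context each -> main molecule wins
        rows = [{"genome": "g", "molecule": "chr", "index": 1, "strand": "+",
                 "family": "ftsZ", "molecule_size": 100},
                {"genome": "g", "molecule": "scaffold9", "index": 1,
                 "strand": "+", "family": "ftsZ", "molecule_size": 5}]
        kar = encode_karyotype(pd.DataFrame(rows))
        assert kar.paralog_log == [("g", "ftsZ", "main-molecule")]
        assert kar.chromosomes == [[("ftsZ", 1)]]

    def test_rule3_orientation(self):
        # both copies on the main molecule, tie on context -> orientation
        rows = order_rows("g", [(f, "+") for f in DCW_FAMILIES[:5]])
        rows.append({"genome": "g", "molecule": "chr", "index": 100,
                     "strand": "-", "family": "ftsZ"})
        rows.append({"genome": "g", "molecule": "chr", "index": 200,
                     "strand": "+", "family": "ftsZ"})
        kar = encode_karyotype(pd.DataFrame(rows))
        assert ("g", "ftsZ", "orientation") in kar.paralog_log
        statuses = classify_status(kar)
        assert statuses["ftsZ"] == "outside"

    def test_direct_rule_cascade(self):
        copies = [{"chrom": 0, "molecule": "chr", "strand": 1, "pos": 5.0},
                  {"chrom": 1, "molecule": "pls", "strand": 1, "pos": 1.0}]
        idx, rule = select_paralog(copies, {0: 10, 1: 0}, "chr", 1)
        assert (idx, rule) == (0, "cluster-context")
        idx, rule = select_paralog(copies, {0: 3, 1: 3}, "chr", 1)
        assert (idx, rule) == (0, "main-molecule")
        copies2 = [dict(c, molecule="chr") for c in copies]
        copies2[1]["strand"] = -1
        idx, rule = select_paralog(copies2, {0: 3, 1: 3}, "chr", 1)
        assert (idx, rule) == (0, "orientation")
        idx, rule = select_paralog([dict(c) for c in copies2[:1]] * 2,
                                   {0: 3}, "chr", 1)
        assert rule == "lowest-coordinate"


class TestClassifyStatus:
    def test_complete_cluster_all_main(self):
        kar = encode_karyotype(pd.DataFrame(order_rows("g", FULL)))
        assert set(classify_status(kar).values()) == {"main-cluster"}

    def test_doublet_is_subcluster(self):
        rows = order_rows("g", [(f, "+") for f in DCW_FAMILIES
                                if f not in ("murC", "murB")])
        rows += order_rows("g", [("murC", "+"), ("murB", "+")],
                           molecule="chr2")
        st = classify_status(encode_karyotype(pd.DataFrame(rows)))
        assert st["murC"] == st["murB"] == "sub-cluster"
        assert st["mraZ"] == "main-cluster"

    def test_fully_dispersed_all_outside(self):
        rows = []
        for i, f in enumerate(DCW_FAMILIES):
            rows += order_rows("g", [(f, "+")], molecule=f"m{i}")
        st = classify_status(encode_karyotype(pd.DataFrame(rows)))
        assert set(st.values()) == {"outside"}

    def test_absent_families_reported(self):
        kar = encode_karyotype(pd.DataFrame(order_rows("g", FULL[:5])))
        st = classify_status(kar)
        assert st["murB"] == "absent"

    def test_tie_for_largest(self):
        rows = order_rows("g", FULL[:4])
        rows += order_rows("g", FULL[4:8], molecule="chr2")
        st = classify_status(encode_karyotype(pd.DataFrame(rows)))
        assert set(st[f] for f, _ in FULL[:8]) == {"main-cluster(tied)"}


class TestAdjacencyParsimony:
    def test_mpr_sets_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for rep in range(12):
            tree = simulate.simulate_tree(n_tips=6, seed=100 + rep)
            tip_states = {tax: int(rng.integers(2)) for tax in tree.taxa}
            got = fitch_state_sets(tree, tip_states)
            want = exhaustive_mpr_sets(tree, tip_states)
            for v in range(tree.n_nodes):
                assert got[v] == want[v], (rep, v)

    def test_adjacency_in_all_tips_present_at_all_ancestors(self):
        tree = simulate.simulate_tree(n_tips=8, seed=1)
        kar = encode_karyotype(pd.DataFrame(order_rows("g", FULL)))
        kars = {tax: EncodedKaryotype(tax, [list(kar.chromosomes[0])])
                for tax in tree.taxa}
        rec = reconstruct_ancestral_adjacencies(tree, kars)
        shared = karyotype_adjacencies(kar)
        for v in range(tree.n_nodes):
            assert shared <= rec.adjacencies[v]

    def test_tips_reproduced_exactly(self):
        tree = simulate.simulate_tree(n_tips=10, seed=6)
        table, kars, _ = simulate.simulate_gene_orders(tree, 0.05, 0.05, seed=7)
        ek = {g: encode_karyotype(sub) for g, sub in table.groupby("genome")}
        rec = reconstruct_ancestral_adjacencies(tree, ek)
        for v in tree.tips():
            assert rec.adjacencies[v] == karyotype_adjacencies(
                ek[tree.tip_labels[v]])

    def test_ancestral_orders_are_linear(self):
        tree = simulate.simulate_tree(n_tips=14, seed=8)
        table, _, _ = simulate.simulate_gene_orders(tree, 0.08, 0.05, seed=9)
        ek = {g: encode_karyotype(sub) for g, sub in table.groupby("genome")}
        rec = reconstruct_ancestral_adjacencies(tree, ek)
        for v in range(tree.n_nodes):
            # no extremity used twice and no family duplicated
            rec.karyotypes[v].validate()
            ends = [e for adj in rec.adjacencies[v] for e in adj]
            assert len(ends) == len(set(ends))

    def test_murA_excision_scenario(self):
        # one subclade lost the murA adjacency: its LCA keeps murA outside the
        # main cluster while the root keeps the complete 17-gene order
        tree = read_newick(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);")
        full = EncodedKaryotype("x", [[(f, 1) for f in DCW_FAMILIES]])
        # excised: murA on its own molecule (order keeps murB after ftsZ)
        rest = [[(f, 1) for f in DCW_FAMILIES if f != "murA"], [("murA", 1)]]
        kars = {}
        for tax in "abcd":
            kars[tax] = EncodedKaryotype(tax, [list(c) for c in rest])
        for tax in "efgh":
            kars[tax] = EncodedKaryotype(tax, [list(full.chromosomes[0])])
        rec = reconstruct_ancestral_adjacencies(tree, kars)
        status = rec.status
        lca_abcd = tree.mrca(["a", "b", "c", "d"])
        assert status.loc[lca_abcd, "murA"] == "outside"
        assert status.loc[tree.root, "murA"] == "main-cluster"
        assert (status.loc[tree.root] == "main-cluster").all()

    def test_missing_karyotype_rejected(self):
        tree = read_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="b"):
            reconstruct_ancestral_adjacencies(
                tree, {"a": EncodedKaryotype("a", [[("ftsZ", 1)]])})


def test_procars_export_format(tmp_path):
    kar = encode_karyotype(pd.DataFrame(order_rows("g", FULL[:3])))
    out = tmp_path / "blocks.txt"
    write_procars_input({"g": kar}, out)
    text = out.read_text()
    assert text.startswith(">g\n")
    assert text.strip().endswith("$")
    assert "mraZ mraW ftsL $" in text
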