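"""Similarity graph, Markov clustering, and category classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import networkx as nx

from orthoflow import (
    build_graph,
    category_counts,
    classify_counts,
    flag_homology_only,
    mcl,
    select_single_copy,
)
from orthoflow.orthology import OrthologGroup
from orthoflow.search import Hit, HitTable

from _oracles import classify_ruletable, mcl_dense

SP12 = [f"s{i:02d}" for i in range(12)]
LIN4 = set(SP12[:4])


def _hit(q, s, e):
    return Hit(q, s, evalue=e, bitscore=50.0, identity=0.8)


class TestBuildGraph:
    def test_reciprocal_weight_is_mean_neg_log10(self):
        t = HitTable(1e-5)
        t.add(_hit("a", "b", 1e-10))
        t.add(_hit("b", "a", 1e-20))
        g = build_graph(t, {"a": "X", "b": "Y"})
        assert g["a"]["b"]["weight"] == pytest.approx(15.0)

    def test_one_directional_hit_gives_no_edge(self):
        t = HitTable(1e-5)
        t.add(_hit("a", "b", 1e-10))
        g = build_graph(t, {"a": "X", "b": "Y"})
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"a", "b"}

    def test_weight_capped(self):
        t = HitTable(1e-5)
        t.add(_hit("a", "b", 1e-200))
        t.add(_hit("b", "a", 1e-200))
        g = build_graph(t, {"a": "X", "b": "Y"})
        assert g["a"]["b"]["weight"] == 200.0


class TestMcl:
    def _graph(self, edges, species=None):
        g = nx.Graph()
        for u, v, w in edges:
            g.add_edge(u, v, weight=w)
        for n in g.nodes:
            g.nodes[n]["species"] = (species or {}).get(n, "X")
        return g

    def test_disjoint_triangles_stay_separate(self):
        edges = [("a", "b", 5), ("b", "c", 5), ("a", "c", 5),
                 ("d", "e", 5), ("e", "f", 5), ("d", "f", 5)]
        res = mcl(self._graph(edges))
        parts = {frozenset(g.members) for g in res.groups}
        assert parts == {frozenset("abc"), frozenset("def")}

    def test_isolated_node_is_singleton(self):
        g = self._graph([("a", "b", 5), ("b", "c", 5), ("a", "c", 5)])
        g.add_node("z", species="X")
        res = mcl(g)
        assert frozenset(["z"]) in {frozenset(gr.members) for gr in res.groups}

    def test_partition_covers_every_node_once(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(20)]
        edges = []
        for _ in range(40):
            u, v = rng.choice(20, size=2, replace=False)
            edges.append((nodes[u], nodes[v], float(rng.uniform(1, 20))))
        g = self._graph(edges)
        res = mcl(g)
        seen = [m for gr in res.groups for m in gr.members]
        assert sorted(seen) == sorted(g.nodes)

    def test_matches_dense_reference_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for trial in range(50):
            n = int(rng.integers(4, 16))
            nodes = [f"n{i:02d}" for i in range(n)]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            edges = []
            for _ in range(int(rng.integers(n, 3 * n))):
                u, v = rng.choice(n, size=2, replace=False)
                w = float(rng.uniform(1, 30))
                edges.append((nodes[u], nodes[v], w))
                g.add_edge(nodes[u], nodes[v], weight=w)
            for nd in g.nodes:
                g.nodes[nd]["species"] = "X"
            got = {frozenset(gr.members) for gr in mcl(g).groups}
            want = mcl_dense(nodes, edges)
            assert got == want, f"trial {trial}"

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl(self._graph([("a", "b", 1)]), inflation=1.0)


class TestClassify:
    def test_absence_in_one_genome_still_single_copy(self):
        copies = {s: 1 for s in SP12}
        copies[SP12[5]] = 0
        assert classify_counts(copies, SP12, LIN4) == "universal-single"

    def test_two_duplicated_genomes_are_multi_copy(self):
        copies = {s: 1 for s in SP12}
        copies[SP12[2]] = 2
        copies[SP12[7]] = 2
        assert classify_counts(copies, SP12, LIN4) == "universal-multi"

    def test_lineage_only_needs_three_lineage_genomes(self):
        copies = {s: 0 for s in SP12}
        for s in list(LIN4)[:3]:
            copies[s] = 1
        assert classify_counts(copies, SP12, LIN4) == "lineage-only"

    def test_half_presence_boundary(self):
        copies = {s: 0 for s in SP12}
        for s in SP12[2:8]:  # 6 of 12, spanning both lineages
            copies[s] = 1
        assert classify_counts(copies, SP12, LIN4) == "present-at-half"
        copies[SP12[7]] = 0  # now 5 of 12
        assert classify_counts(copies, SP12, LIN4) == "patchy"

    def test_single_species_duplication_is_specific(self):
        copies = {s: 0 for s in SP12}
        copies[SP12[0]] = 4
        assert classify_counts(copies, SP12, LIN4) == "species-specific"

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=12, max_size=12))
    def test_matches_rule_table_and_is_exclusive(self, vec):
        copies = dict(zip(SP12, vec))
        if sum(vec) == 0:
            with pytest.raises(ValueError):
                classify_counts(copies, SP12, LIN4)
            return
        got = classify_counts(copies, SP12, LIN4)
        assert got == classify_ruletable(copies, SP12, LIN4)

    def test_lineage_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            classify_counts({"a": 1, "b": 1}, ["a", "b"], {"z"})


class TestHomologyOnly:
    def test_unclustered_gene_with_hit_flagged(self):
        t = HitTable(1e-5)
        t.add(_hit("lone", "other", 1e-8))
        groups = [OrthologGroup("OG1", ["lone"], {"lone": "X"})]
        flagged = flag_homology_only(["lone", "silent"], t, groups)
        assert flagged == {"lone"}

    def test_grouped_gene_not_flagged(self):
        t = HitTable(1e-5)
        t.add(_hit("a", "b", 1e-8))
        sp = {m: "X" for m in "abcde"}
        groups = [OrthologGroup("OG1", list("abcde"), sp)]
        assert flag_homology_only(list("abcde"), t, groups) == set()


class TestCountsAndSelection:
    def test_counts_sum_to_proteome_sizes(self, small_truth):
        # perfect clustering: the truth mapping itself
        sp_of = {g.gene_id: g.species for g in small_truth.genes}
        by_fam = {}
        for g in small_truth.genes:
            by_fam.setdefault(g.family_id, []).append(g.gene_id)
        groups = [
            OrthologGroup(fid, sorted(ms), {m: sp_of[m] for m in ms})
            for fid, ms in sorted(by_fam.items())
        ]
        species = sorted({g.species for g in small_truth.genes})
        labels = {g.group_id: classify_counts(g.copy_counts(species), species) for g in groups}
        table = category_counts(groups, labels, species, sp_of)
        sizes = {sp: sum(1 for g in small_truth.genes if g.species == sp) for sp in species}
        for sp in species:
            assert table.loc[sp].sum() == sizes[sp]

    def test_truth_mapping_recovers_truth_categories(self, small_truth):
        """Oracle short-circuit: replacing clustering by the truth mapping
        must reproduce the generator's category labels exactly."""
        species = sorted({g.species for g in small_truth.genes})
        sp_of = {g.gene_id: g.species for g in small_truth.genes}
        by_fam = {}
        for g in small_truth.genes:
            by_fam.setdefault(g.family_id, []).append(g.gene_id)
        truth_cat = {f.family_id: f.category for f in small_truth.families}
        for fid, ms in by_fam.items():
            grp = OrthologGroup(fid, ms, {m: sp_of[m] for m in ms})
            assert classify_counts(grp.copy_counts(species), species) == truth_cat[fid]

    def test_unlabelled_group_rejected(self):
        g = OrthologGroup("OG1", ["a", "b"], {"a": "X", "b": "Y"})
        with pytest.raises(ValueError):
            category_counts([g], {}, ["X", "Y"])

    @pytest.mark.parametrize(
        "counts,strict_ok,tolerant_ok",
        [
            ((1, 1, 1, 1), True, True),
            ((1, 1, 1, 0), False, True),
            ((1, 2, 1, 1), False, True),
            ((2, 2, 1, 1), False, False),
        ],
    )
    def test_single_copy_selection_modes(self, counts, strict_ok, tolerant_ok):
        species = ["A", "B", "C", "D"]
        members = []
        sp_of = {}
        for sp, c in zip(species, counts):
            for k in range(c):
                gid = f"{sp}|F|g{k}"
                members.append(gid)
                sp_of[gid] = sp
        g = OrthologGroup("OG1", members, sp_of)
        assert bool(select_single_copy([g], species, strict=True)) == strict_ok
        assert bool(select_single_copy([g], species, strict=False)) == tolerant_ok
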