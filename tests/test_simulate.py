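"""Simulator: newick handling, family sampling, and the divergence model."""

import numpy as np
import pytest

from orthoflow import (
    CopyParams,
    classify_counts,
    evolve_family,
    parse_newick,
    sample_families,
    simulate_truth,
    write_truth,
)
from orthoflow.seqio import AMINO_ACIDS, read_fasta
from orthoflow.simulate import FamilySpec, expected_identity, read_truth_table


class TestNewick:
    def test_parse_three_leaf_tree(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert t.species == ["A", "B", "C"]
        assert t.path_distance("A", "B") == pytest.approx(2.0)
        assert t.path_distance("A", "C") == pytest.approx(4.0)

    def test_round_trip_preserves_topology_and_lengths(self):
        text = "((A:1,B:1):1,C:2);"
        t1 = parse_newick(text)
        t2 = parse_newick(t1.to_newick())
        assert t1.species == t2.species
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            assert t1.path_distance(a, b) == pytest.approx(t2.path_distance(a, b))

    @pytest.mark.parametrize(
        "bad",
        [
            "((A:1,B:1):1,C:-2);",  # negative length
            "((A:1,A:1):1,C:2);",  # duplicate label
            "((A:1,B:1):1;",  # unbalanced parentheses
            "(A:1,B:1);",  # too few leaves
        ],
    )
    def test_invalid_trees_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_newick(bad)


class TestSampleFamilies:
    def test_pure_universal_single_forces_copy_one(self, four_species_tree):
        fams = sample_families(four_species_tree, {"universal-single": 1.0}, 10, seed=1)
        assert len(fams) == 10
        for f in fams:
            assert all(c == 1 for c in f.copies.values())

    def test_species_specific_confined_to_one_species(self, four_species_tree):
        fams = sample_families(four_species_tree, {"species-specific": 1.0}, 5, seed=2)
        for f in fams:
            assert sum(1 for c in f.copies.values() if c >= 1) == 1

    def test_every_spec_classifies_to_its_category(self):
        tree = parse_newick(
            "(((A:.1,B:.1):.1,(C:.1,D:.1):.1):.1,((E:.1,F:.1):.1,(G:.1,H:.1):.1):.1);"
        )
        props = {c: 1 / 6 for c in (
            "universal-single", "universal-multi", "lineage-only",
            "species-specific", "present-at-half", "patchy",
        )}
        fams = sample_families(tree, props, 120, seed=3, lineage=["A", "B", "C", "D"])
        for f in fams:
            got = classify_counts(f.copies, tree.species, {"A", "B", "C", "D"})
            assert got == f.category

    def test_mixture_frequencies_within_three_se(self, four_species_tree):
        props = {"universal-single": 0.5, "species-specific": 0.5}
        fams = sample_families(four_species_tree, props, 1000, seed=4)
        n_single = sum(f.category == "universal-single" for f in fams)
        se = np.sqrt(0.5 * 0.5 * 1000)
        assert abs(n_single - 500) <= 3 * se

    def test_bad_proportions_rejected(self, four_species_tree):
        with pytest.raises(ValueError):
            sample_families(four_species_tree, {"universal-single": 0.7}, 5)
        with pytest.raises(ValueError):
            sample_families(four_species_tree, {"lineage-only": 1.0}, 5)


class TestEvolution:
    def test_zero_branch_lengths_give_identical_leaves(self):
        t = parse_newick("((A:0,B:0):0,C:0);")
        fam = FamilySpec("F1", "universal-single", {"A": 1, "B": 1, "C": 1})
        seqs = evolve_family(t, fam, seed=0, root_length=80)
        assert seqs["A"] == seqs["B"] == seqs["C"]

    def test_same_seed_reproduces_sequences(self, asym_tree):
        fam = FamilySpec("F1", "universal-single", {"A": 1, "B": 1, "F": 1})
        s1 = evolve_family(asym_tree, fam, seed=7, root_length=100)
        s2 = evolve_family(asym_tree, fam, seed=7, root_length=100)
        assert s1 == s2

    def test_mean_identity_matches_closed_form(self):
        # D = 1 between A and B; uniform pi: expectation e^-1 + (1-e^-1)/20
        t = parse_newick("((A:0.5,B:0.5):0.1,C:0.1);")
        fam = FamilySpec("F1", "universal-single", {"A": 1, "B": 1, "C": 1})
        idents = []
        for seed in range(40):
            seqs = evolve_family(t, fam, seed=seed, root_length=300)
            idents.append(
                np.mean([x == y for x, y in zip(seqs["A"][0], seqs["B"][0])])
            )
        exp = expected_identity(1.0)
        assert exp == pytest.approx(np.exp(-1) + (1 - np.exp(-1)) / 20)
        se = np.std(idents, ddof=1) / np.sqrt(len(idents))
        assert abs(np.mean(idents) - exp) <= 3 * se

    def test_identity_decreases_with_distance(self):
        # ladder of distances: identity must be ordered in expectation
        t = parse_newick("(((A:0.05,B:0.05):0.2,C:0.3):0.3,D:0.5);")
        fam = FamilySpec("F1", "universal-single", {s: 1 for s in "ABCD"})
        means = {pair: [] for pair in (("A", "B"), ("A", "C"), ("A", "D"))}
        for seed in range(30):
            seqs = evolve_family(t, fam, seed=seed, root_length=300)
            for x, y in means:
                means[(x, y)].append(
                    np.mean([p == q for p, q in zip(seqs[x][0], seqs[y][0])])
                )
        ab, ac, ad = (np.mean(means[p]) for p in (("A", "B"), ("A", "C"), ("A", "D")))
        assert ab > ac > ad

    def test_duplicated_copies_evolve_independently(self, asym_tree):
        fam = FamilySpec("F1", "universal-multi", {"A": 3, "B": 1, "F": 2})
        seqs = evolve_family(asym_tree, fam, seed=1, root_length=200)
        assert len(seqs["A"]) == 3 and len(seqs["F"]) == 2
        assert len({tuple(s) for s in seqs["A"]}) == 3  # all copies distinct

    def test_alphabet_is_canonical(self, small_truth):
        for g in small_truth.genes[:20]:
            assert set(g.seq) <= set(AMINO_ACIDS)


class TestTruthOutput:
    def test_write_truth_artifacts(self, small_truth, tmp_path):
        written = write_truth(small_truth, tmp_path)
        species = {g.species for g in small_truth.genes}
        assert set(written) >= species | {"truth"}
        rows = read_truth_table(written["truth"])
        assert len(rows) == len(small_truth.genes)

    def test_fasta_round_trip_preserves_sequences(self, small_truth, tmp_path):
        write_truth(small_truth, tmp_path)
        by_species = {}
        for g in small_truth.genes:
            by_species.setdefault(g.species, {})[g.gene_id] = g.seq
        for sp, expect in by_species.items():
            back = {r.id: r.seq for r in read_fasta(tmp_path / f"{sp}.faa")}
            assert back == expect

    def test_absent_species_has_no_records(self, four_species_tree, tmp_path):
        truth = simulate_truth(
            four_species_tree, 6, {"species-specific": 1.0}, seed=5, root_length=60
        )
        write_truth(truth, tmp_path)
        rows = read_truth_table(tmp_path / "truth.tsv")
        present = {(r[1], r[2]) for r in rows}
        for fam in truth.families:
            for sp, c in fam.copies.items():
                assert ((sp, fam.family_id) in present) == (c >= 1)

    def test_fixed_seed_bit_identical_files(self, four_species_tree, tmp_path):
        kw = dict(
            n_families=5, category_proportions={"universal-single": 1.0},
            seed=9, root_length=80,
        )
        t1 = simulate_truth(four_species_tree, **kw)
        t2 = simulate_truth(four_species_tree, **kw)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_truth(t1, d1)
        write_truth(t2, d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()
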