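"""Similarity search: isoform filtering, local alignment, E-values, hits."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthoflow import (
    align_local,
    all_against_all,
    evalue,
    filter_longest_isoform,
    read_hits,
)
from orthoflow.search import Hit, HitTable
from orthoflow.seqio import FastaRecord, Proteome

from _oracles import local_align_bruteforce


class TestIsoformFilter:
    def test_longest_isoform_kept(self):
        p = Proteome("X", [FastaRecord("G1.1", "A" * 100), FastaRecord("G1.2", "A" * 150)])
        out = filter_longest_isoform(p)
        assert [r.id for r in out.records] == ["G1.2"]

    def test_no_isoforms_passes_through(self):
        p = Proteome("X", [FastaRecord("G1", "AC"), FastaRecord("G2", "DE")])
        assert filter_longest_isoform(p).ids() == ["G1", "G2"]

    def test_equal_length_tie_takes_smaller_id(self):
        p = Proteome("X", [FastaRecord("G1.2", "ACDE"), FastaRecord("G1.1", "MNPQ")])
        assert filter_longest_isoform(p).ids() == ["G1.1"]


class TestAlignLocal:
    def test_self_alignment_scores_diagonal_sum(self):
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        seq = "HEAGAWGHEE"
        score, ident, length = align_local(seq, seq)
        assert score == pytest.approx(sum(m[c, c] for c in seq))
        assert ident == 1.0 and length == len(seq)

    def test_disjoint_low_scoring_sequences_give_zero(self):
        # no positive substitution value between any of these residue pairs
        score, ident, length = align_local("PPPP", "GGGG")
        assert (score, ident, length) == (0.0, 0.0, 0)

    def test_unknown_letters_rejected_or_floored(self):
        with pytest.raises(ValueError):
            align_local("ACDJ", "ACDE")  # J outside the matrix alphabet
        score, _, _ = align_local("ACDJ", "ACDE", on_unknown="min")
        assert score > 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACDEWK", min_size=2, max_size=5),
        st.text(alphabet="ACDEWK", min_size=2, max_size=5),
    )
    def test_matches_exhaustive_enumeration(self, a, b):
        """The DP score equals brute-force enumeration over all local
        alignment paths (small gap penalties so gaps actually occur)."""
        score, _, _ = align_local(a, b, gap_open=1.0, gap_extend=1.0)
        assert score == pytest.approx(local_align_bruteforce(a, b, 1.0, 1.0))

    def test_score_symmetric(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        assert align_local(a, b)[0] == align_local(b, a)[0]


class TestEvalue:
    def test_score_shift_shrinks_e_by_exp_factor(self):
        e1 = evalue(50, 100, 100)
        e2 = evalue(60, 100, 100)
        assert e2 / e1 == pytest.approx(math.exp(-0.267 * 10))

    def test_direct_formula(self):
        assert evalue(50, 100, 100, K=0.041, lam=0.267) == pytest.approx(
            0.041 * 1e4 * math.exp(-13.35)
        )

    def test_lambda_to_zero_limit(self):
        assert evalue(1000, 1, 1, K=1.0, lam=1e-12) == pytest.approx(1.0)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            evalue(10, 100, 100, K=0.0)
        with pytest.raises(ValueError):
            evalue(10, 0, 100)


class TestAllAgainstAll:
    def test_identical_single_gene_proteomes_reciprocal_hits(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
        p1 = Proteome("X", [FastaRecord("X|g1", seq)])
        p2 = Proteome("Y", [FastaRecord("Y|g1", seq)])
        table = all_against_all([p1, p2])
        assert len(table) == 2
        assert table.get("X|g1", "Y|g1").identity == 1.0

    def test_hit_count_upper_bound(self, small_truth):
        prots = [
            Proteome(p.species, p.records[:5]) for p in small_truth.proteomes()
        ]
        n = sum(len(p) for p in prots)
        table = all_against_all(prots)
        assert len(table) <= n * (n - 1)

    def test_orthologs_at_small_distance_all_hit(self, small_truth):
        prots = [Proteome(p.species, p.records[:6]) for p in small_truth.proteomes()]
        table = all_against_all(prots)
        by_fam = {}
        for p in prots:
            for r in p.records:
                by_fam.setdefault(r.id.split("|")[1], []).append(r.id)
        for fam, members in by_fam.items():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    assert table.get(a, b) is not None, (a, b)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            all_against_all([Proteome("X", []), Proteome("Y", [FastaRecord("g", "ACD")])])


class TestHitTable:
    def test_threshold_filtering_is_idempotent(self):
        t = HitTable(1e-5)
        t.add(Hit("a", "b", evalue=1e-10, bitscore=50, identity=0.9))
        t.add(Hit("a", "c", evalue=1e-3, bitscore=20, identity=0.5))  # above cut
        assert len(t) == 1
        refiltered = HitTable(1e-5)
        for h in t:
            refiltered.add(h)
        assert len(refiltered) == len(t)

    def test_best_by_evalue_kept(self):
        t = HitTable(1e-5)
        t.add(Hit("a", "b", evalue=1e-10, bitscore=50, identity=0.9))
        t.add(Hit("a", "b", evalue=1e-20, bitscore=80, identity=0.95))
        assert t.get("a", "b").evalue == 1e-20

    def test_self_hits_never_stored(self):
        t = HitTable(1e-5)
        assert not t.add(Hit("a", "a", evalue=1e-50, bitscore=99, identity=1.0))


class TestReadHits:
    def _write(self, path, rows):
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))

    def test_threshold_applied_on_read(self, tmp_path):
        fp = tmp_path / "h.tsv"
        base = [90.0, 100, 5, 0, 1, 100, 1, 100]
        self._write(fp, [
            ["a", "b", *base, 1e-10, 200.0],
            ["b", "a", *base, 1e-12, 210.0],
            ["a", "c", *base, 1e-3, 30.0],
        ])
        table = read_hits(fp)
        assert len(table) == 2

    def test_duplicate_rows_collapse_to_best(self, tmp_path):
        fp = tmp_path / "h.tsv"
        base = [90.0, 100, 5, 0, 1, 100, 1, 100]
        self._write(fp, [
            ["a", "b", *base, 1e-10, 200.0],
            ["a", "b", *base, 1e-20, 250.0],
        ])
        table = read_hits(fp)
        assert len(table) == 1
        assert table.get("a", "b").evalue == 1e-20

    def test_wrong_column_count_names_line(self, tmp_path):
        fp = tmp_path / "h.tsv"
        fp.write_text("a\tb\t90.0\n")
        with pytest.raises(ValueError, match=":1:"):
            read_hits(fp)

    def test_zero_evalue_floored(self, tmp_path):
        fp = tmp_path / "h.tsv"
        base = [99.0, 300, 1, 0, 1, 300, 1, 300]
        self._write(fp, [["a", "b", *base, 0.0, 900.0]])
        assert read_hits(fp).get("a", "b").evalue == 1e-200
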