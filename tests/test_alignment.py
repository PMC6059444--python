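import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from contamscreen.alignment import (
    AlignmentParams,
    HitRecord,
    HitsFormatError,
    ProteinDatabase,
    ProteinRecord,
    build_kmer_index,
    decode_kmer,
    kmer_codes,
    local_align,
    read_hits_tsv,
    read_kmer_index,
    search_read,
    six_frame_translate,
    write_hits_tsv,
    write_kmer_index,
)
from contamscreen.genome import PseudoRead, revcomp
from contamscreen.taxonomy import TaxonNode, TaxonomyTree

from conftest import lca_oracle

_B62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a: str, b: str, open_cost=12, extend_cost=1) -> float:
    """Independent Gotoh local alignment (first gap residue costs
    ``open_cost``, each further residue ``extend_cost``)."""
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            s = _B62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def naive_revtrans(pep: str) -> str:
    table = unambiguous_dna_by_id[11]
    pick = {}
    for codon, aa in sorted(table.forward_table.items()):
        pick.setdefault(aa, codon)
    return "".join(pick[aa] for aa in pep)


class TestKmerCodes:
    def test_canonical_under_reverse_complement(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        fwd = sorted(kmer_codes(seq, 21).tolist())
        rev = sorted(kmer_codes(revcomp(seq), 21).tolist())
        assert fwd == rev

    def test_n_kmers_skipped(self):
        assert len(kmer_codes("ACGTNACGT", 5)) == 0
        assert len(kmer_codes("ACGTNACGTA", 5)) == 1

    def test_decode_inverts_encode(self):
        for kmer in ("AAAAA", "ACGTC", "TTTTT"):
            code = kmer_codes(kmer + "G" * 0, 5)
            canon = min(kmer, revcomp(kmer))
            assert decode_kmer(int(code[0]), 5) == canon


class TestKmerIndex:
    def make_tree(self):
        return TaxonomyTree(
            [
                TaxonNode("r", None, "root"),
                TaxonNode("p", "r", "genus"),
                TaxonNode("a", "p", "species"),
                TaxonNode("b", "p", "species"),
                TaxonNode("c", "r", "species"),
            ],
            focal_id="p",
        )

    def test_unique_kmer_maps_to_its_genome_taxon(self):
        tree = self.make_tree()
        idx = build_kmer_index([("gA", "a", "ACGTACGTACGTACGTACGTACGTA")], tree, k=21)
        assert idx.lookup("ACGTACGTACGTACGTACGTA") == "a"

    def test_shared_kmer_maps_to_lca(self):
        tree = self.make_tree()
        shared = "ACGTACGTACGTACGTACGTA"
        idx = build_kmer_index(
            [("gA", "a", shared + "GGGGG"), ("gB", "b", "TTTTT" + shared)], tree, k=21
        )
        assert idx.lookup(shared) == "p"

    def test_matches_brute_force_enumeration(self):
        tree = self.make_tree()
        rng = np.random.default_rng(7)
        genomes = [
            (f"g{t}", t, "".join(rng.choice(list("ACGT"), size=300)))
            for t in ("a", "b", "c")
        ]
        k = 5
        idx = build_kmer_index(genomes, tree, k=k)
        # independent oracle: enumerate windows, canonicalise by string,
        # collect taxa per kmer, reduce by path-intersection LCA
        expected: dict[str, set] = {}
        for _, taxon, seq in genomes:
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                expected.setdefault(min(w, revcomp(w)), set()).add(taxon)
        assert len(idx) == len(expected)
        for kmer, taxa in expected.items():
            assert idx.lookup(kmer) == lca_oracle(tree, taxa)

    def test_invariant_under_reference_reverse_complement(self):
        tree = self.make_tree()
        rng = np.random.default_rng(9)
        seqs = {t: "".join(rng.choice(list("ACGT"), size=400)) for t in ("a", "b")}
        fwd = build_kmer_index([(f"g{t}", t, s) for t, s in seqs.items()], tree, k=11)
        rev = build_kmer_index(
            [(f"g{t}", t, revcomp(s)) for t, s in seqs.items()], tree, k=11
        )
        assert np.array_equal(fwd.kmers, rev.kmers)
        assert [fwd.taxon_ids[i] for i in fwd.taxa] == [rev.taxon_ids[i] for i in rev.taxa]

    def test_round_trip_tsv(self, tmp_path):
        tree = self.make_tree()
        rng = np.random.default_rng(3)
        idx = build_kmer_index(
            [("gA", "a", "".join(rng.choice(list("ACGT"), size=100)))], tree, k=9
        )
        p = tmp_path / "index.tsv"
        write_kmer_index(idx, p)
        back = read_kmer_index(p)
        assert back.k == idx.k
        assert np.array_equal(back.kmers, idx.kmers)
        assert back.source_genomes == idx.source_genomes


class TestSixFrame:
    def test_forward_frame(self):
        assert six_frame_translate("ATGAAA")[1] == "MK"

    def test_reverse_frame(self):
        assert six_frame_translate("TTTCAT")[-1] == "MK"

    def test_stop_emitted_as_star(self):
        assert six_frame_translate("TAA")[1] == "*"

    def test_partial_codons_dropped(self):
        frames = six_frame_translate("ATGAAAC")
        assert frames[1] == "MK"
        assert frames[2] == "*N"


class TestLocalAlign:
    def test_self_alignment_matches_oracle(self):
        pep = "MKVLAATGGDERWQHILKNPSTYFCMKVLAA"[:30]
        res = local_align(pep, pep)
        assert res.identity == pytest.approx(100.0)
        assert res.aln_len == 30
        assert res.raw_score == pytest.approx(sw_affine_oracle(pep, pep))
        params = AlignmentParams()
        assert res.bit_score == pytest.approx(params.bit_score(res.raw_score))

    def test_unrelated_homopolymers_no_hit(self):
        assert local_align("KKKK", "DDDD") is None

    def test_single_substitution_identity(self):
        pep = "MKVLAATGGDERWQHILKNPSTYFCMKVLA"
        mutated = pep[:10] + "W" + pep[11:]
        res = local_align(pep, mutated)
        assert res.identity == pytest.approx(100.0 * 29 / 30)
        assert res.raw_score == pytest.approx(sw_affine_oracle(pep, mutated))

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(17)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(8):
            a = "".join(rng.choice(aas, size=int(rng.integers(15, 35))))
            b = "".join(rng.choice(aas, size=int(rng.integers(15, 35))))
            res = local_align(a, b)
            oracle = sw_affine_oracle(a, b)
            if res is None:
                assert oracle <= 0
            else:
                assert res.raw_score == pytest.approx(oracle)

    def test_score_symmetric_in_arguments(self):
        a, b = "MKVLAATGGDERWQHILK", "MKVLWATGGDERQHILKN"
        assert local_align(a, b).raw_score == pytest.approx(local_align(b, a).raw_score)


class TestSearchRead:
    def make_db(self, seed_k=0):
        prot = "MKVLAATGGDERWQHILKNPSTYFCMKVLAADERWQHILKNPSTYF"
        other = "WWWWYYYYFFFFHHHHRRRRDDDDEEEEKKKK"
        return ProteinDatabase(
            [
                ProteinRecord("pA", "gA", "a", prot),
                ProteinRecord("pB", "gB", "b", prot),  # identical paralogue
                ProteinRecord("pC", "gC", "c", other),
            ],
            seed_k=seed_k,
        ), prot

    def test_read_from_coding_region_hits_source_protein(self):
        db, prot = self.make_db()
        read = PseudoRead("r1", "s", 0, 3 * len(prot), naive_revtrans(prot))
        hits = search_read(read, db)
        assert hits[0].subject_id in ("pA", "pB")
        assert hits[0].identity == pytest.approx(100.0)

    def test_all_n_read_yields_nothing(self):
        db, _ = self.make_db()
        read = PseudoRead("r2", "s", 0, 90, "N" * 90)
        assert search_read(read, db) == []

    def test_paralogues_ordered_by_bit_then_id(self):
        db, prot = self.make_db()
        read = PseudoRead("r3", "s", 0, 3 * len(prot), naive_revtrans(prot))
        hits = search_read(read, db)
        top2 = [h.subject_id for h in hits[:2]]
        assert top2 == ["pA", "pB"]
        assert hits[0].bit_score == pytest.approx(hits[1].bit_score)

    def test_seeded_search_agrees_with_exhaustive_on_strong_hits(self):
        db0, prot = self.make_db(seed_k=0)
        db5, _ = self.make_db(seed_k=5)
        read = PseudoRead("r4", "s", 0, 3 * len(prot), naive_revtrans(prot))
        strong0 = [(h.subject_id, h.bit_score) for h in search_read(read, db0, min_bit=50)]
        strong5 = [(h.subject_id, h.bit_score) for h in search_read(read, db5, min_bit=50)]
        assert strong0 == strong5


class TestHitsTsv:
    def make_hits(self):
        return [
            HitRecord("q1", "sA", "gA", "tA", 98.5, 80, 150.0, 1e-30),
            HitRecord("q2", "sB", "gB", "tB", 75.0, 40, 85.5, 1e-10),
        ]

    def test_round_trip(self, tmp_path):
        p = tmp_path / "hits.tsv"
        hits = self.make_hits()
        write_hits_tsv(hits, p)
        back = read_hits_tsv(p)
        assert [(h.query_id, h.subject_id, h.subject_genome_id, h.subject_taxon_id) for h in back] == [
            (h.query_id, h.subject_id, h.subject_genome_id, h.subject_taxon_id) for h in hits
        ]
        assert back[0].bit_score == pytest.approx(150.0, abs=0.1)

    def test_12_column_with_mapping(self, tmp_path):
        p = tmp_path / "h12.tsv"
        p.write_text("q1\tsA\t98.5\t80\t1\t0\t1\t80\t1\t80\t1e-30\t150.0\n")
        back = read_hits_tsv(p, subject_map={"sA": ("gA", "tA")})
        assert back[0].subject_genome_id == "gA" and back[0].subject_taxon_id == "tA"

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q1\tsA\t98.5\n")
        with pytest.raises(HitsFormatError, match=":1"):
            read_hits_tsv(p)
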