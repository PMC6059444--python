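import numpy as np
import pytest

from contamscreen.alignment import HitRecord, KmerIndex, kmer_codes
from contamscreen.classify import (
    KmerClassifierConfig,
    ProteinLcaConfig,
    classify_read_kmer,
    classify_read_protein,
    kraken_na_mask,
    profile_assembly,
)
from contamscreen.genome import PseudoRead
from contamscreen.taxonomy import Label, ReadLabel


def hit(taxon, bit, genome=None, subject=None):
    return HitRecord(
        query_id="q",
        subject_id=subject or f"s_{taxon}_{bit}",
        subject_genome_id=genome or f"g_{taxon}",
        subject_taxon_id=taxon,
        identity=90.0,
        aln_len=50,
        bit_score=bit,
        e_value=1e-9,
    )


def toy_index(read_seq: str, assignment: list[str], k: int = 21) -> KmerIndex:
    """Index mapping the read's i-th canonical kmer to assignment[i]."""
    codes = kmer_codes(read_seq, k)
    assert len(codes) == len(assignment)
    taxon_ids = sorted(set(assignment))
    pos = {t: i for i, t in enumerate(taxon_ids)}
    order = np.argsort(codes)
    return KmerIndex(
        k=k,
        kmers=codes[order],
        taxa=np.asarray([pos[assignment[i]] for i in order], dtype=np.int32),
        taxon_ids=taxon_ids,
        source_genomes={"ref1"},
    )


def unique_kmer_read(rng, n_kmers: int, k: int = 21) -> str:
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=n_kmers + k - 1))
        if len(np.unique(kmer_codes(seq, k))) == n_kmers:
            return seq


class TestKmerClassifier:
    def test_unique_leaf_read_full_confidence(self, toy_tree):
        rng = np.random.default_rng(2)
        seq = unique_kmer_read(rng, 50)
        index = toy_index(seq, ["s1"] * 50)
        read = PseudoRead("r", "sc", 0, len(seq), seq)
        label = classify_read_kmer(read, index, toy_tree, KmerClassifierConfig())
        assert label.label is Label.FOCAL and label.taxon_id == "s1"

    def test_no_hits_unclassified(self, toy_tree):
        rng = np.random.default_rng(3)
        seq = unique_kmer_read(rng, 30)
        other = unique_kmer_read(np.random.default_rng(4), 30)
        index = toy_index(other, ["s1"] * 30)
        read = PseudoRead("r", "sc", 0, len(seq), seq)
        # different sequence: essentially no shared canonical kmers
        if set(kmer_codes(seq, 21).tolist()) & set(index.kmers.tolist()):
            pytest.skip("accidental kmer collision")
        assert classify_read_kmer(read, index, toy_tree).label is Label.UNCLASSIFIED

    def test_sixty_forty_split_picks_majority_leaf(self, toy_tree):
        # 100 kmers: 60 unique to s1, 40 to its sibling s2; threshold 0.5
        rng = np.random.default_rng(5)
        seq = unique_kmer_read(rng, 100)
        index = toy_index(seq, ["s1"] * 60 + ["s2"] * 40)
        read = PseudoRead("r", "sc", 0, len(seq), seq)
        label = classify_read_kmer(
            read, index, toy_tree, KmerClassifierConfig(confidence=0.5)
        )
        assert label.taxon_id == "s1"

    def test_confidence_promotion_to_parent(self, toy_tree):
        rng = np.random.default_rng(6)
        seq = unique_kmer_read(rng, 100)
        index = toy_index(seq, ["s1"] * 60 + ["s2"] * 40)
        read = PseudoRead("r", "sc", 0, len(seq), seq)
        # 0.6 < c <= 1.0 forces promotion to the genus (covers all hits)
        label = classify_read_kmer(
            read, index, toy_tree, KmerClassifierConfig(confidence=0.9)
        )
        assert label.taxon_id == "g1"

    def test_promotion_past_root_gives_unclassified(self, toy_tree):
        rng = np.random.default_rng(7)
        seq = unique_kmer_read(rng, 100)
        # only 10 of 100 kmers hit at all: root confidence 0.1
        hit_part = seq[: 10 + 20]
        index = toy_index(hit_part, ["s1"] * 10)
        read = PseudoRead("r", "sc", 0, len(seq), seq)
        label = classify_read_kmer(
            read, index, toy_tree, KmerClassifierConfig(confidence=0.5)
        )
        assert label.label is Label.UNCLASSIFIED

    def test_read_shorter_than_k_rejected(self, toy_tree):
        rng = np.random.default_rng(8)
        seq = unique_kmer_read(rng, 5)
        index = toy_index(seq, ["s1"] * 5)
        short = PseudoRead("r", "sc", 0, 10, "ACGTACGTAC")
        with pytest.raises(ValueError):
            classify_read_kmer(short, index, toy_tree)


class TestProteinLca:
    def test_single_hit_labels_its_taxon(self, toy_tree):
        label = classify_read_protein([hit("s3", 120.0)], toy_tree)
        assert label.label is Label.CONTAMINANT and label.taxon_id == "s3"

    def test_top_fraction_excludes_94_bit_hit(self, toy_tree):
        label = classify_read_protein(
            [hit("s1", 100.0), hit("s3", 94.0)], toy_tree, ProteinLcaConfig()
        )
        # 94 < 0.95 x 100: only the s1 hit remains
        assert label.taxon_id == "s1" and label.label is Label.FOCAL

    def test_sibling_collapse_can_reach_unknown(self, toy_tree):
        label = classify_read_protein(
            [hit("s1", 100.0), hit("s3", 96.0)], toy_tree, ProteinLcaConfig()
        )
        # LCA(s1, s3) = dom, an ancestor of the focal clade
        assert label.label is Label.UNKNOWN and label.taxon_id == "dom"

    def test_only_self_match_is_unclassified(self, toy_tree):
        label = classify_read_protein(
            [hit("s1", 150.0, genome="gSELF")],
            toy_tree,
            ProteinLcaConfig(),
            self_genome_id="gSELF",
        )
        assert label.label is Label.UNCLASSIFIED

    def test_min_bit_filter(self, toy_tree):
        label = classify_read_protein([hit("s1", 79.9)], toy_tree, ProteinLcaConfig())
        assert label.label is Label.UNCLASSIFIED

    def test_raising_top_fraction_moves_label_leafward(self, toy_tree):
        hits = [hit("s1", 100.0), hit("s2", 97.0)]
        loose = classify_read_protein(hits, toy_tree, ProteinLcaConfig(top_fraction=0.95))
        tight = classify_read_protein(hits, toy_tree, ProteinLcaConfig(top_fraction=0.99))
        assert loose.taxon_id == "g1" and tight.taxon_id == "s1"


class TestProfile:
    def test_contamination_percentages(self, toy_tree):
        labels = [ReadLabel(Label.CONTAMINANT, "s3")] * 10 + [
            ReadLabel(Label.FOCAL, "s1")
        ] * 90
        prof = profile_assembly("a", labels, toy_tree)
        assert prof.contamination == pytest.approx(10.0)
        assert prof.per_phylum["p2"] == pytest.approx(10.0)

    def test_zero_contamination(self, toy_tree):
        prof = profile_assembly("a", [ReadLabel(Label.FOCAL, "s1")] * 100, toy_tree)
        assert prof.contamination == 0.0

    def test_fractions_partition_to_100(self, toy_tree):
        rng = np.random.default_rng(11)
        pool = [
            ReadLabel(Label.FOCAL, "s1"),
            ReadLabel(Label.CONTAMINANT, "s4"),
            ReadLabel(Label.UNKNOWN, "dom"),
            ReadLabel(Label.UNCLASSIFIED, None),
        ]
        labels = [pool[i] for i in rng.integers(0, 4, size=173)]
        prof = profile_assembly("a", labels, toy_tree)
        total = prof.focal + prof.contaminant + prof.unknown + prof.unclassified
        assert total == pytest.approx(100.0, abs=1e-9)
        assert sum(prof.per_phylum.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_read_set_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            profile_assembly("a", [], toy_tree)


class TestNaMask:
    def test_database_genome_flagged(self, toy_tree):
        rng = np.random.default_rng(12)
        seq = unique_kmer_read(rng, 10)
        index = toy_index(seq, ["s1"] * 10)
        assert kraken_na_mask("ref1", index) is True
        assert kraken_na_mask("other", index) is False
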