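import numpy as np
import pytest

from contamscreen.genome import Assembly, Scaffold, revcomp
from contamscreen.markers import (
    MarkerFamily,
    MarkerHit,
    MarkerReference,
    SsuLocus,
    classify_marker,
    classify_marker_hits,
    classify_ssu_loci,
    detect_rprot_orthologues,
    detect_ssu,
    read_marker_panel,
    redundancy_estimate,
    rprot_contamination,
    ssu_contamination,
    write_marker_panel,
)
from contamscreen.taxonomy import Label, ReadLabel, UNCLASSIFIED_READ


def single_scaffold(universe, genome_id, flip=False):
    seq = universe.genomes[genome_id].sequence
    if flip:
        seq = revcomp(seq)
    return Assembly(genome_id + ("_rc" if flip else ""), [Scaffold("chr", seq)])


class TestDetectSsu:
    def test_finds_every_implanted_copy(self, small_universe):
        genome = next(iter(small_universe.genomes.values()))
        asm = single_scaffold(small_universe, genome.genome_id)
        loci = detect_ssu(asm, small_universe.ssu_family)
        implanted = [l for l in genome.loci if l.kind == "ssu"]
        assert len(loci) == len(implanted)
        for found in loci:
            assert any(
                abs(found.start - l.start) <= 10 and abs(found.end - l.end) <= 10
                for l in implanted
            )

    def test_reverse_complemented_scaffold_still_detected(self, small_universe):
        genome = next(iter(small_universe.genomes.values()))
        fwd = single_scaffold(small_universe, genome.genome_id)
        rev = single_scaffold(small_universe, genome.genome_id, flip=True)
        assert len(detect_ssu(rev, small_universe.ssu_family)) == len(
            detect_ssu(fwd, small_universe.ssu_family)
        )

    def test_no_ssu_like_region_means_no_loci(self, small_universe):
        rng = np.random.default_rng(0)
        asm = Assembly("rand", [Scaffold("c", "".join(rng.choice(list("ACGT"), size=20_000)))])
        assert detect_ssu(asm, small_universe.ssu_family) == []

    def test_best_hit_classification_labels_source(self, small_universe):
        genome = next(
            g for g in small_universe.genomes.values() if g.phylum_id != "p1"
        )
        asm = single_scaffold(small_universe, genome.genome_id)
        loci = detect_ssu(asm, small_universe.ssu_family)
        classify_ssu_loci(loci, small_universe.taxonomy)
        assert all(l.label.label is Label.CONTAMINANT for l in loci)


class TestSsuContamination:
    def locus(self, label):
        return SsuLocus("s", 0, 1500, "+", None, 99.0, label)

    def test_one_foreign_of_two(self):
        loci = [
            self.locus(ReadLabel(Label.CONTAMINANT, "x")),
            self.locus(ReadLabel(Label.FOCAL, "y")),
        ]
        assert ssu_contamination(loci) == pytest.approx(50.0)

    def test_no_predicted_is_missing(self):
        assert ssu_contamination([]) is None

    def test_two_foreign_of_three(self):
        loci = [self.locus(ReadLabel(Label.CONTAMINANT, "x"))] * 2 + [
            self.locus(ReadLabel(Label.FOCAL, "y"))
        ]
        assert ssu_contamination(loci) == pytest.approx(66.67, abs=0.01)


class TestDetectRprot:
    def test_clean_genome_yields_every_family_once(self, small_universe):
        genome = next(iter(small_universe.genomes.values()))
        asm = single_scaffold(small_universe, genome.genome_id)
        hits = detect_rprot_orthologues(asm, small_universe.rprot_families)
        per_family = {}
        for h in hits:
            per_family[h.family_id] = per_family.get(h.family_id, 0) + 1
        assert per_family == {
            f.family_id: 1 for f in small_universe.rprot_families
        }

    def test_focal_genome_markers_classified_focal(self, small_universe):
        genome = small_universe.genomes[small_universe.focal_genomes()[0]]
        asm = single_scaffold(small_universe, genome.genome_id)
        hits = detect_rprot_orthologues(asm, small_universe.rprot_families)
        classify_marker_hits(hits, small_universe.taxonomy)
        focal = sum(1 for h in hits if h.label.label is Label.FOCAL)
        assert focal / len(hits) >= 0.95

    def test_random_sequence_yields_no_candidates(self, small_universe):
        rng = np.random.default_rng(1)
        asm = Assembly("rand", [Scaffold("c", "".join(rng.choice(list("ACGT"), size=30_000)))])
        assert detect_rprot_orthologues(asm, small_universe.rprot_families) == []

    def test_candidate_assigned_to_nearest_family_only(self, small_universe):
        # a genuine member of one family must not create a hit in another:
        # the single-best-hit screen assigns it to its own family
        fam = small_universe.rprot_families[0]
        ref = fam.references[0]
        nt = naive_gene(ref.sequence)
        asm = Assembly("one_gene", [Scaffold("c", "ACGT" * 30 + nt + "TGCA" * 30)])
        hits = detect_rprot_orthologues(asm, small_universe.rprot_families)
        assert len(hits) == 1 and hits[0].family_id == fam.family_id


def naive_gene(pep: str) -> str:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]
    pick = {}
    for codon, aa in sorted(table.forward_table.items()):
        pick.setdefault(aa, codon)
    return "".join(pick[aa] for aa in pep)


class TestClassifyMarker:
    def ref(self, i, taxon):
        return MarkerReference(f"ref{i}", f"g{i}", taxon, "A" * 50)

    def hit(self, neighbours):
        return MarkerHit("s", 0, 300, "+", "fam", 200.0, neighbours)

    def test_three_focal_neighbours_focal(self, toy_tree):
        nb = [(self.ref(i, t), 95.0 - i, 50) for i, t in enumerate(["s1", "s2", "g1"])]
        assert classify_marker(self.hit(nb), toy_tree).label is Label.FOCAL

    def test_below_identity_threshold_unclassified(self, toy_tree):
        nb = [(self.ref(i, "s1"), 65.0, 50) for i in range(3)]
        assert classify_marker(self.hit(nb), toy_tree) is UNCLASSIFIED_READ

    def test_three_contaminant_neighbours_contaminant(self, toy_tree):
        nb = [(self.ref(i, t), 90.0 - i, 50) for i, t in enumerate(["s3", "s4", "g2"])]
        label = classify_marker(self.hit(nb), toy_tree)
        assert label.label is Label.CONTAMINANT and label.taxon_id == "g2"

    def test_short_alignment_neighbours_excluded(self, toy_tree):
        nb = [(self.ref(0, "s3"), 95.0, 20), (self.ref(1, "s1"), 90.0, 50)]
        label = classify_marker(self.hit(nb), toy_tree)
        assert label.label is Label.FOCAL  # the 20-aa neighbour is dropped


class TestRprotContamination:
    def hit(self, label):
        return MarkerHit("s", 0, 300, "+", "fam", 100.0, [], label)

    def test_no_foreign(self):
        hits = [self.hit(ReadLabel(Label.FOCAL, "x"))] * 40
        assert rprot_contamination(hits) == 0.0

    def test_twenty_of_fortyfive(self):
        hits = [self.hit(ReadLabel(Label.CONTAMINANT, "x"))] * 20 + [
            self.hit(ReadLabel(Label.FOCAL, "y"))
        ] * 25
        assert rprot_contamination(hits) == pytest.approx(44.44, abs=0.01)

    def test_unclassified_excluded_from_denominator(self):
        hits = [self.hit(ReadLabel(Label.CONTAMINANT, "x"))] * 2 + [self.hit(UNCLASSIFIED_READ)] * 8
        assert rprot_contamination(hits) == pytest.approx(100.0)

    def test_no_classified_is_missing(self):
        assert rprot_contamination([self.hit(UNCLASSIFIED_READ)]) is None


class TestRedundancy:
    def hits_for(self, counts, spacing=20_000):
        hits = []
        pos = 0
        for fam, c in counts.items():
            for _ in range(c):
                hits.append(MarkerHit("s", pos, pos + 300, "+", fam, 100.0))
                pos += spacing
        return hits

    def test_all_single_copy(self):
        fams = [f"m{i}" for i in range(10)]
        comp, cont = redundancy_estimate(self.hits_for({f: 1 for f in fams}), fams)
        assert (comp, cont) == (100.0, 0.0)

    def test_triplicate_markers_exceed_100(self):
        fams = [f"m{i}" for i in range(10)]
        comp, cont = redundancy_estimate(self.hits_for({f: 3 for f in fams}), fams)
        assert (comp, cont) == (100.0, 200.0)

    def test_half_panel_present(self):
        fams = [f"m{i}" for i in range(10)]
        comp, cont = redundancy_estimate(
            self.hits_for({f: 1 for f in fams[:5]}), fams
        )
        assert (comp, cont) == (50.0, 0.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            redundancy_estimate([], [])

    def test_collocation_merges_nearby_duplicates(self):
        hits = [
            MarkerHit("s", 0, 300, "+", "m0", 100.0),
            MarkerHit("s", 1000, 1300, "+", "m0", 100.0),  # within 5 kb
            MarkerHit("s", 50_000, 50_300, "+", "m0", 100.0),
        ]
        _, cont_plain = redundancy_estimate(hits, ["m0"])
        _, cont_merged = redundancy_estimate(hits, ["m0"], collocation_window=5000)
        assert cont_plain == pytest.approx(200.0)
        assert cont_merged == pytest.approx(100.0)


def test_marker_panel_round_trip(tmp_path, small_universe):
    path = tmp_path / "panel.fa"
    families = small_universe.rprot_families[:3]
    write_marker_panel(families, path)
    back = read_marker_panel(path)
    assert [f.family_id for f in back] == [f.family_id for f in families]
    for fa, fb in zip(families, back):
        assert [(r.ref_id, r.genome_id, r.taxon_id, r.sequence) for r in fa.references] == [
            (r.ref_id, r.genome_id, r.taxon_id, r.sequence) for r in fb.references
        ]
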