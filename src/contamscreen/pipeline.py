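"""End-to-end screening: run all six estimators on an assembly.

A ``ReferencePack`` bundles the search substrates built once per
reference database (signature-kmer index, seeded proteome, marker
panels); ``screen_assembly`` then produces the six-method contamination
score vector for any query assembly, plus the per-read labels and marker
hits the genome maps and decontamination steps reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentParams, KmerIndex, ProteinDatabase, build_kmer_index, search_read
from .binning import BinningConfig, cluster_segments, largest_group_contamination
from .classify import (
    AssemblyProfile,
    KmerClassifierConfig,
    ProteinLcaConfig,
    classify_read_kmer,
    classify_read_protein,
    kraken_na_mask,
    profile_assembly,
)
from .consensus import METHODS
from .genome import Assembly, PseudoRead, make_pseudoreads, make_segments
from .markers import (
    MarkerFamily,
    MarkerHit,
    SsuLocus,
    classify_marker_hits,
    classify_ssu_loci,
    detect_rprot_orthologues,
    detect_ssu,
    marker_estimates,
)
from .taxonomy import ReadLabel, TaxonomyTree


@dataclass
class ReferencePack:
    taxonomy: TaxonomyTree
    kmer_index: KmerIndex
    protein_db: ProteinDatabase
    rprot_families: list[MarkerFamily]
    ssu_family: MarkerFamily
    params: AlignmentParams = field(default_factory=AlignmentParams)

    @property
    def panel_family_ids(self) -> list[str]:
        return [f.family_id for f in self.rprot_families]


def build_reference_pack(
    universe,
    exclude: frozenset[str] | set[str] = frozenset(),
    k: int = 21,
    seed_k: int = 5,
) -> ReferencePack:
    """Build all search substrates from a simulated universe (or any
    object exposing the same reference accessors)."""
    return ReferencePack(
        taxonomy=universe.taxonomy,
        kmer_index=build_kmer_index(universe.reference_genomes(exclude), universe.taxonomy, k=k),
        protein_db=ProteinDatabase(universe.proteome(exclude), seed_k=seed_k),
        rprot_families=universe.marker_families(exclude),
        ssu_family=universe.ssu_references(exclude),
    )


@dataclass
class ScreenResult:
    assembly_id: str
    scores: dict[str, Optional[float]]
    kmer_profile: AssemblyProfile
    protein_profile: AssemblyProfile
    kmer_labels: list[tuple[PseudoRead, ReadLabel]]
    protein_labels: list[tuple[PseudoRead, ReadLabel]]
    ssu_loci: list[SsuLocus]
    rprot_hits: list[MarkerHit]


def screen_assembly(
    assembly: Assembly,
    pack: ReferencePack,
    self_genome_id: Optional[str] = None,
    kmer_config: KmerClassifierConfig = KmerClassifierConfig(),
    protein_config: ProteinLcaConfig = ProteinLcaConfig(),
    binning_config: BinningConfig = BinningConfig(),
    methods: Sequence[str] = METHODS,
) -> ScreenResult:
    """Estimate contamination with each of the six methods.

    ``self_genome_id`` names the assembly's own reference genome for
    protein-LCA self-match exclusion.  The kmer method's score is missing
    (None) for assemblies that are part of the kmer reference database.
    Methods not listed in ``methods`` are skipped and reported missing.
    """
    reads = make_pseudoreads(assembly)
    scores: dict[str, Optional[float]] = {m: None for m in METHODS}

    kmer_labels: list[tuple[PseudoRead, ReadLabel]] = []
    kmer_profile = protein_profile = None
    if "kmer" in methods:
        labels = [
            classify_read_kmer(r, pack.kmer_index, pack.taxonomy, kmer_config)
            for r in reads
            if r.end - r.start >= kmer_config.k
        ]
        used = [r for r in reads if r.end - r.start >= kmer_config.k]
        kmer_labels = list(zip(used, labels))
        kmer_profile = profile_assembly(assembly.assembly_id, labels, pack.taxonomy)
        if kraken_na_mask(assembly.assembly_id, pack.kmer_index):
            scores["kmer"] = None
        else:
            scores["kmer"] = kmer_profile.contamination

    protein_labels: list[tuple[PseudoRead, ReadLabel]] = []
    if "protein" in methods:
        labels = []
        for r in reads:
            hits = search_read(
                r,
                pack.protein_db,
                pack.params,
                min_bit=protein_config.min_bit,
                with_alignment=False,
            )
            labels.append(
                classify_read_protein(hits, pack.taxonomy, protein_config, self_genome_id)
            )
        protein_labels = list(zip(reads, labels))
        protein_profile = profile_assembly(assembly.assembly_id, labels, pack.taxonomy)
        scores["protein"] = protein_profile.contamination

    ssu_loci: list[SsuLocus] = []
    if "rRNA" in methods:
        ssu_loci = detect_ssu(assembly, pack.ssu_family)
        classify_ssu_loci(ssu_loci, pack.taxonomy)

    rprot_hits: list[MarkerHit] = []
    if "rprot" in methods or "redundancy" in methods:
        rprot_hits = detect_rprot_orthologues(assembly, pack.rprot_families, pack.params)
        classify_marker_hits(rprot_hits, pack.taxonomy)

    if ssu_loci or rprot_hits or "rprot" in methods or "rRNA" in methods:
        est = marker_estimates(ssu_loci, rprot_hits, pack.panel_family_ids)
        if "rRNA" in methods:
            scores["rRNA"] = est.ssu_contamination
        if "rprot" in methods:
            scores["rprot"] = est.rprot_contamination
        if "redundancy" in methods:
            scores["redundancy"] = est.redundancy_contamination

    if "binning" in methods:
        segments = make_segments(assembly, min_len=binning_config.min_segment)
        if len(segments) >= 2:
            assignment = cluster_segments(segments, binning_config)
            scores["binning"] = largest_group_contamination(assignment)

    return ScreenResult(
        assembly_id=assembly.assembly_id,
        scores=scores,
        kmer_profile=kmer_profile,  # type: ignore[arg-type]
        protein_profile=protein_profile,  # type: ignore[arg-type]
        kmer_labels=kmer_labels,
        protein_labels=protein_labels,
        ssu_loci=ssu_loci,
        rprot_hits=rprot_hits,
    )


def score_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Assemblies x methods score matrix with NaN for missing values."""
    rows = {
        r.assembly_id: {m: (np.nan if r.scores[m] is None else r.scores[m]) for m in METHODS}
        for r in results
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(METHODS)]
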