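"""Per-read classifiers and their aggregation into assembly profiles.

Two genome-wide classifiers operate on 250-nt pseudo-reads:

* a signature-kmer classifier: each kmer votes for the taxon stored in the
  reference index, the root-path with the highest summed vote wins, and a
  confidence threshold promotes weakly supported labels toward the root;
* a protein-LCA classifier over translated-search hits: hits within a
  fraction of the best bit score are collapsed by LCA, with self-matches
  (hits to the assembly's own reference genome) excluded.

Assembly-level contamination is the percentage of pseudo-reads labelled
CONTAMINANT out of *all* pseudo-reads; classified-yet-uninformative
(UNKNOWN) and unclassified reads stay in the denominator but count toward
neither side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignment import HitRecord, KmerIndex, kmer_codes
from .genome import PseudoRead
from .taxonomy import (
    Label,
    ReadLabel,
    TaxonomyTree,
    UNCLASSIFIED_READ,
    label_of,
    lca,
)


@dataclass(frozen=True)
class KmerClassifierConfig:
    k: int = 21
    confidence: float = 0.04

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@dataclass(frozen=True)
class ProteinLcaConfig:
    min_bit: float = 80.0
    top_fraction: float = 0.95
    min_hits: int = 1
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")


@dataclass
class AssemblyProfile:
    assembly_id: str
    n_reads: int
    focal: float
    contaminant: float
    unknown: float
    unclassified: float
    per_phylum: dict[str, float] = field(default_factory=dict)

    @property
    def contamination(self) -> float:
        return self.contaminant


def classify_read_kmer(
    read: PseudoRead,
    index: KmerIndex,
    taxonomy: TaxonomyTree,
    config: KmerClassifierConfig = KmerClassifierConfig(),
) -> ReadLabel:
    """Classify one pseudo-read by signature-kmer voting.

    The candidate label is the leaf-most node maximising the summed hit
    count along its root-path (ties resolved by the LCA of the tied
    nodes).  Confidence is the fraction of the read's valid (ACGT-only)
    kmers hitting nodes within the clade rooted at the label; while it
    falls below the threshold the label is promoted to its parent, and a
    read failing at the root is UNCLASSIFIED.
    """
    if read.end - read.start < config.k:
        raise ValueError(f"read {read.read_id!r} shorter than k={config.k}")
    codes = kmer_codes(read.sequence, config.k)
    n_valid = len(codes)
    if n_valid == 0:
        return UNCLASSIFIED_READ
    taxon_idx = index.lookup_codes(codes)
    hit_idx = taxon_idx[taxon_idx >= 0]
    if len(hit_idx) == 0:
        return UNCLASSIFIED_READ
    counts: dict[str, int] = {}
    for ti, n in zip(*np.unique(hit_idx, return_counts=True)):
        counts[index.taxon_ids[int(ti)]] = int(n)
    # root-path score per candidate node: hits on its ancestors-or-self
    candidates = {node for tid in counts for node in taxonomy.path_to_root(tid)}
    path_score = {
        v: sum(counts.get(u, 0) for u in taxonomy.path_to_root(v)) for v in candidates
    }
    best = max(path_score.values())
    tied = [node for node, s in path_score.items() if s == best]
    max_depth = max(taxonomy.depth(n) for n in tied)
    leafmost = [n for n in tied if taxonomy.depth(n) == max_depth]
    label = leafmost[0] if len(leafmost) == 1 else lca(taxonomy, leafmost)

    def confidence_at(node: str) -> float:
        in_clade = sum(n for tid, n in counts.items() if taxonomy.is_ancestor(node, tid))
        return in_clade / n_valid

    while confidence_at(label) < config.confidence:
        parent = taxonomy.parent(label)
        if parent is None:
            return UNCLASSIFIED_READ
        label = parent
    return label_of(taxonomy, label)


def classify_read_protein(
    hits: Sequence[HitRecord],
    taxonomy: TaxonomyTree,
    config: ProteinLcaConfig = ProteinLcaConfig(),
    self_genome_id: Optional[str] = None,
) -> ReadLabel:
    """MEGAN-like LCA of the best protein hits of one pseudo-read.

    Self-matches (subject genome equal to the query assembly's own source
    genome) are dropped first, then hits below ``min_bit``; of the rest,
    hits within ``top_fraction`` of the best bit score are collapsed by
    LCA.
    """
    kept = [
        h
        for h in hits
        if not (config.exclude_self and self_genome_id is not None and h.subject_genome_id == self_genome_id)
        and h.bit_score >= config.min_bit
    ]
    if not kept:
        return UNCLASSIFIED_READ
    best = max(h.bit_score for h in kept)
    top = [h for h in kept if h.bit_score >= config.top_fraction * best]
    if len(top) < config.min_hits:
        return UNCLASSIFIED_READ
    return label_of(taxonomy, lca(taxonomy, {h.subject_taxon_id for h in top}))


def profile_assembly(
    assembly_id: str,
    read_labels: Sequence[ReadLabel],
    taxonomy: TaxonomyTree,
    phylum_rank: str = "phylum",
) -> AssemblyProfile:
    """Aggregate per-read labels into an assembly contamination profile.

    The per-phylum breakdown assigns each FOCAL/CONTAMINANT read to the
    nearest phylum-rank ancestor of its taxon; reads whose taxon has no
    phylum-rank ancestor (e.g. domain-level assignments) are pooled under
    "unknown", and no-hit reads under "unclassified".
    """
    if not read_labels:
        raise ValueError("profile of empty read set")
    n = len(read_labels)
    tally = {lab: 0 for lab in Label}
    per_phylum: dict[str, int] = {}
    for rl in read_labels:
        tally[rl.label] += 1
        if rl.label in (Label.FOCAL, Label.CONTAMINANT):
            assert rl.taxon_id is not None
            phylum = taxonomy.ancestor_at_rank(rl.taxon_id, phylum_rank)
            name = taxonomy.nodes[phylum].name or phylum if phylum else "unknown"
            per_phylum[name] = per_phylum.get(name, 0) + 1
        elif rl.label is Label.UNKNOWN:
            per_phylum["unknown"] = per_phylum.get("unknown", 0) + 1
        else:
            per_phylum["unclassified"] = per_phylum.get("unclassified", 0) + 1
    return AssemblyProfile(
        assembly_id=assembly_id,
        n_reads=n,
        focal=100.0 * tally[Label.FOCAL] / n,
        contaminant=100.0 * tally[Label.CONTAMINANT] / n,
        unknown=100.0 * tally[Label.UNKNOWN] / n,
        unclassified=100.0 * tally[Label.UNCLASSIFIED] / n,
        per_phylum={k: 100.0 * v / n for k, v in per_phylum.items()},
    )


def kraken_na_mask(assembly_id: str, index: KmerIndex) -> bool:
    """True when the assembly was used to build the kmer index, in which
    case its kmer-method score is uninformative and treated as missing."""
    return assembly_id in index.source_genomes


def write_read_classifications(labels: Iterable[tuple[str, ReadLabel]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#read_id\ttaxon_id\tlabel\n")
        for read_id, rl in labels:
            fh.write(f"{read_id}\t{rl.taxon_id or '-'}\t{rl.label.value}\n")
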